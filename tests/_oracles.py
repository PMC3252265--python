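"""Independent numerical oracles shared across test modules."""

import numpy as np
from scipy.linalg import solve_banded


def fixation_oracle(r, N):
    """First-step-analysis linear solve of the Moran birth-death walk.

    h_i = fixation probability from i mutants; h_0 = 0, h_N = 1;
    P(i -> i+1) = [r i/(r i + N - i)] (N-i)/N, P(i -> i-1) mirrored.
    """
    if N == 1:
        return 1.0
    n = N - 1
    ab = np.zeros((3, n))
    b = np.zeros(n)
    for idx, i in enumerate(range(1, N)):
        pu = (r * i / (r * i + N - i)) * ((N - i) / N)
        pdn = ((N - i) / (r * i + N - i)) * (i / N)
        ab[1, idx] = pu + pdn
        if idx + 1 < n:
            ab[0, idx + 1] = -pu
        if idx - 1 >= 0:
            ab[2, idx - 1] = -pdn
        if i + 1 == N:
            b[idx] = pu
    return float(solve_banded((1, 1), ab, b)[0])
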