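"""Independent oracles used by the test suite.

Deliberately naive implementations (explicit double loops, raw pinhole
arithmetic) kept free of any package internals, so they can arbitrate.
"""

import numpy as np


def brute_force_anova(matrix):
    """Two-way crossed ANOVA sums of squares by explicit double loops."""
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    grand = 0.0
    for i in range(n):
        for j in range(k):
            grand += m[i, j]
    grand /= n * k
    row_means = [sum(m[i, j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(m[i, j] for i in range(n)) / n for j in range(k)]
    ss_rows = sum(k * (rm - grand) ** 2 for rm in row_means)
    ss_cols = sum(n * (cm - grand) ** 2 for cm in col_means)
    ss_total = 0.0
    for i in range(n):
        for j in range(k):
            ss_total += (m[i, j] - grand) ** 2
    ss_error = ss_total - ss_rows - ss_cols
    return {
        "ss_rows": ss_rows, "ss_cols": ss_cols, "ss_error": ss_error,
        "ss_total": ss_total,
        "ms_rows": ss_rows / (n - 1), "ms_cols": ss_cols / (k - 1),
        "ms_error": ss_error / ((n - 1) * (k - 1)),
        "n": n, "k": k,
    }


def brute_force_icc_a_k(matrix):
    """Absolute-agreement average-measures ICC from the brute-force ANOVA."""
    an = brute_force_anova(matrix)
    return (an["ms_rows"] - an["ms_error"]) / (
        an["ms_rows"] + (an["ms_cols"] - an["ms_error"]) / an["n"])


def brute_force_eta2(matrix):
    an = brute_force_anova(matrix)
    return an["ss_cols"] / an["ss_total"]


def brute_force_sem(matrix, icc):
    an = brute_force_anova(matrix)
    sd = (an["ss_total"] / (an["n"] - 1)) ** 0.5
    return sd * (1.0 - icc) ** 0.5


def pinhole_project(point, cam_pos, look_sign, f_px, principal):
    """Raw pinhole arithmetic for a y-axis-aligned camera."""
    x, y, z = point
    d = look_sign * (y - cam_pos[1])
    u = principal[0] + look_sign * f_px[0] * (x - cam_pos[0]) / d
    v = principal[1] - f_px[1] * (z - cam_pos[2]) / d
    return u, v
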