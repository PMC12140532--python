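"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def icc_2_1_oracle(pred, truth):
    """ICC(2,1) from raw two-way ANOVA sums of squares (k = 2 raters)."""
    x = np.column_stack([truth, pred]).astype(float)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def window_count_oracle(duration_s, window_s=10.0, hop_s=1.0):
    """Enumerate window start positions; bouts must exceed the window."""
    count = 0
    if duration_s > window_s:
        j = 0
        while j * hop_s + window_s <= duration_s + 1e-9:
            count += 1
            j += 1
    return count
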