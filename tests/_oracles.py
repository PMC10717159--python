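"""Independent brute-force peak oracle built on scipy's prominence machinery.

Used to cross-check the package's own extrema enumeration: scipy computes the
prominent local minima/maxima; the contraction-counting conventions
(relaxation-separated minima, one maximum between adjacent minima, flanking
maxima) are re-stated here from their documented definitions.
"""

import numpy as np
from scipy.signal import find_peaks


def brute_force_peaks(smoothed: np.ndarray, prominence: float):
    """Return (lower_indices, upper_indices) for a smoothed deviation signal."""
    lower, _ = find_peaks(-smoothed, prominence=prominence)
    upper_cand, _ = find_peaks(smoothed, prominence=prominence)

    # adjacent minima with no prominent maximum between collapse to the
    # deepest (earliest on ties)
    if lower.size > 1:
        keys = np.searchsorted(upper_cand, lower)
        kept = []
        for key in dict.fromkeys(keys.tolist()):
            group = lower[keys == key]
            kept.append(int(group[np.argmin(smoothed[group])]))
        lower = np.asarray(kept, dtype=int)

    if lower.size == 0:
        upper = list(upper_cand)
    else:
        upper = []
        pre = upper_cand[upper_cand < lower[0]]
        if pre.size:
            upper.append(int(pre[np.argmax(smoothed[pre])]))
        for a, b in zip(lower[:-1], lower[1:]):
            upper.append(int(a + 1 + np.argmax(smoothed[a + 1 : b])))
        post = upper_cand[upper_cand > lower[-1]]
        if post.size:
            upper.append(int(post[np.argmax(smoothed[post])]))
    return lower, np.asarray(sorted(upper), dtype=int)
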