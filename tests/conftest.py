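import numpy as np
import pytest

from enhancerkit.blending import fast_registry


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_registry():
    return fast_registry()


# ---------------------------------------------------------------------------
# Independent brute-force oracles (shared by unit and acceptance tests).
# These stay deliberately naive: per-base boolean masks, exhaustive run
# enumeration, O(n^2) pairwise comparisons.
# ---------------------------------------------------------------------------

def perbase_intersection_oracle(peaks_a, peaks_b, chrom_len):
    """Per-base AND of coverage masks -> list of (start, end) intervals."""
    mask_a = np.zeros(chrom_len, dtype=bool)
    mask_b = np.zeros(chrom_len, dtype=bool)
    for _, s, e in peaks_a:
        mask_a[s:e] = True
    for _, s, e in peaks_b:
        mask_b[s:e] = True
    both = mask_a & mask_b
    intervals = []
    start = None
    for i, v in enumerate(both):
        if v and start is None:
            start = i
        elif not v and start is not None:
            intervals.append((start, i))
            start = None
    if start is not None:
        intervals.append((start, chrom_len))
    return intervals


def exhaustive_call_oracle(probs, multiplier=0.3):
    """Enumerate all maximal retained runs; argmax mean, leftmost on ties.

    Returns (first_window_idx, last_window_idx, mean_prob, threshold).
    """
    probs = np.asarray(probs, dtype=float)
    t = probs.mean() - multiplier * probs.std()
    retained = probs >= t
    runs = []
    i = 0
    n = len(probs)
    while i < n:
        if retained[i]:
            j = i
            while j + 1 < n and retained[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    best = None
    for first, last in runs:
        mean = probs[first : last + 1].mean()
        if best is None or mean > best[2]:
            best = (first, last, mean)
    return best[0], best[1], best[2], t


def pairwise_auroc_oracle(y_true, y_prob):
    """O(n^2) probability-of-correct-ranking with 0.5 credit for ties."""
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob, dtype=float)
    pos = y_prob[y_true == 1]
    neg = y_prob[y_true == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
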