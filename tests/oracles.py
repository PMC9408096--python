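"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: exact rational
arithmetic for the confusion-matrix metrics, O(P*N) pair counting for
ROC-AUC, a character-by-character sliding window for k-mer counts, and a
position-by-position running sum for the enrichment score.
"""

from fractions import Fraction
import math


def metrics_oracle(tp, tn, fp, fn):
    """Confusion metrics with exact rationals; degenerate ratios -> 0."""
    def ratio(num, den):
        return Fraction(num, den) if den else Fraction(0)

    total = tp + tn + fp + fn
    accuracy = ratio(tp + tn, total)
    sensitivity = ratio(tp, tp + fn)
    specificity = ratio(tn, tn + fp)
    precision = ratio(tp, tp + fp)
    f1 = ratio(2 * precision * sensitivity, precision + sensitivity) \
        if (precision + sensitivity) else Fraction(0)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return {"accuracy": float(accuracy), "sensitivity": float(sensitivity),
            "specificity": float(specificity), "f1": float(f1), "mcc": mcc}


def roc_auc_oracle(labels, scores):
    """All positive-negative pair comparison; ties score 1/2."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = Fraction(0)
    for p in pos:
        for n in neg:
            if p > n:
                total += 1
            elif p == n:
                total += Fraction(1, 2)
    return float(total / (len(pos) * len(neg)))


def kmer_oracle(sequence, k):
    """Naive sliding-window counts over the DNA alphabet, skipping windows
    containing N; returns frequencies divided by len(sequence) in
    lexicographic k-mer order."""
    from itertools import product

    words = ["".join(p) for p in product("ACGT", repeat=k)]
    counts = {w: 0 for w in words}
    L = len(sequence)
    for i in range(L - k + 1):
        window = sequence[i:i + k]
        if "N" in window:
            continue
        counts[window] += 1
    return [counts[w] / L for w in words]


def enrichment_oracle(scores, is_hit, weight_exponent=1.0):
    """Position-by-position running sum; returns (es, running list)."""
    n = len(scores)
    hits = [i for i in range(n) if is_hit[i]]
    n_miss = n - len(hits)
    denom = sum(abs(scores[i]) ** weight_exponent for i in hits)
    running = []
    cur = 0.0
    for i in range(n):
        if is_hit[i]:
            cur += abs(scores[i]) ** weight_exponent / denom
        else:
            cur -= 1.0 / n_miss
        running.append(cur)
    es = max(running, key=abs)
    return es, running
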