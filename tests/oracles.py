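"""Independent explicit-loop oracles for the feature operators and helpers.

Deliberately written as plain Python loops over samples, with no shared code
with the package implementation, so agreement is a genuine cross-check.
"""

import math


def mav_oracle(x):
    total = 0.0
    for v in x:
        total += abs(v)
    return total / len(x)


def wl_oracle(x):
    total = 0.0
    for i in range(len(x) - 1):
        total += abs(x[i + 1] - x[i])
    return total


def zc_oracle(x, thr):
    count = 0
    for i in range(len(x) - 1):
        sign_change = (x[i] > 0 and x[i + 1] < 0) or (x[i] < 0 and x[i + 1] > 0)
        if sign_change and abs(x[i] - x[i + 1]) >= thr:
            count += 1
    return count


def ssc_oracle(x, thr):
    count = 0
    for i in range(1, len(x) - 1):
        if (x[i] - x[i - 1]) * (x[i] - x[i + 1]) >= thr:
            count += 1
    return count


def sis_oracle(x):
    total = 0.0
    for v in x:
        total += v * v
    return total


def norm_rsd1_oracle(x):
    total = 0.0
    for i in range(len(x) - 1):
        d = x[i + 1] - x[i]
        total += d * d
    return math.sqrt(total / len(x))


def norm_rsd2_oracle(x):
    total = 0.0
    for i in range(len(x) - 2):
        d = x[i + 2] - 2 * x[i + 1] + x[i]
        total += d * d
    return math.sqrt(total / len(x))


def norm_logdet_oracle(x, eps=1e-12):
    total = 0.0
    for v in x:
        total += math.log(abs(v) + eps)
    return math.exp(total / len(x)) / len(x)


def m_msr_oracle(x):
    total = 0.0
    for v in x:
        total += math.sqrt(abs(v))
    return total / len(x)


def m_asm_oracle(x):
    k = len(x)
    total = 0.0
    for n in range(1, k + 1):  # 1-based sample index
        e = 0.50 if (n >= 0.25 * k and n <= 0.75 * k) else 0.75
        total += abs(x[n - 1]) ** e
    return abs(total) / k


def rms_oracle(x):
    total = 0.0
    for v in x:
        total += v * v
    return math.sqrt(total / len(x))


def count_windows_oracle(n_samples, window, step):
    """Slide-and-count enumeration of full windows."""
    count = 0
    start = 0
    while start + window <= n_samples:
        count += 1
        start += step
    return count


def accuracy_oracle(counts):
    correct = 0
    total = 0
    for i, row in enumerate(counts):
        for j, v in enumerate(row):
            total += v
            if i == j:
                correct += v
    return 100.0 * correct / total


def mcc_oracle(counts, j):
    k = len(counts)
    tp = counts[j][j]
    fn = sum(counts[j][c] for c in range(k)) - tp
    fp = sum(counts[r][j] for r in range(k)) - tp
    tn = sum(sum(row) for row in counts) - tp - fn - fp
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def per_class_recall_oracle(counts):
    out = []
    for i, row in enumerate(counts):
        total = sum(row)
        out.append(100.0 * row[i] / total if total else 0.0)
    return out
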