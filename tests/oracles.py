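"""Independent brute-force reimplementations of every preprocessing stage.

Pure-python loops over row tuples, written without reference to the package
implementation, used as the comparison oracle on small fixtures.
"""

from collections import Counter, defaultdict


def oracle_series(lab_rows):
    """lab_rows: iterable of (hadm_id, charttime, value) -> {hadm: [values]} time-ordered."""
    by_adm = defaultdict(list)
    for pos, (hadm, t, v) in enumerate(lab_rows):
        by_adm[hadm].append((t, pos, v))
    return {h: [v for _, _, v in sorted(rows)] for h, rows in by_adm.items()}


def oracle_cohort(series_by_adm, threshold=125.0):
    return sorted(h for h, s in series_by_adm.items() if max(s) >= threshold)


def oracle_peak_last(series):
    return max(series), series[-1]


def oracle_normalize(value):
    capped = value if value <= 500.0 else 500.0
    x = (capped - 125.0) / 375.0
    return min(max(x, 0.0), 1.0)


def oracle_age_flags(age):
    edges = [18, 30, 40, 50, 60, 70]
    flags = [False] * 6
    idx = 0
    for i, lo in enumerate(edges):
        if age >= lo:
            idx = i
    flags[idx] = True
    return flags


def oracle_gender_flags(g):
    return [g == "M", g == "F"]


def oracle_provider(poe_rows, hadm_id):
    """poe_rows: iterable of (hadm_id, provider_id); max count, ties to smallest id."""
    counts = Counter(p for h, p in poe_rows if h == hadm_id)
    best = max(counts.values())
    return sorted(p for p, c in counts.items() if c == best)[0]


def oracle_provider_codes(provider_ids):
    return {p: i for i, p in enumerate(sorted(set(provider_ids)))}


def oracle_rmse(preds, targets):
    return (sum((p - t) ** 2 for p, t in zip(preds, targets)) / len(preds)) ** 0.5
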