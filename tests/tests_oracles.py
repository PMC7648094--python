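"""Shared brute-force oracle implementations, kept independent of the package."""


def oracle_cluster(intervals, merge_gap):
    """Repeated all-pairs merging of (start, end) intervals; O(n^2) or worse.

    Returns sorted (start, end, n_members) tuples.
    """
    groups = [{"start": s, "end": e, "n": 1} for s, e in intervals]
    merged = True
    while merged:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a, b = groups[i], groups[j]
                gap = max(a["start"], b["start"]) - min(a["end"], b["end"]) - 1
                if gap <= merge_gap:
                    a["start"] = min(a["start"], b["start"])
                    a["end"] = max(a["end"], b["end"])
                    a["n"] += b["n"]
                    del groups[j]
                    merged = True
                    break
            if merged:
                break
    return sorted((g["start"], g["end"], g["n"]) for g in groups)


def oracle_repeats(seq, min_unit=1, max_unit=6, min_total_len=20):
    """Every qualifying tandem interval found by exhaustive extension, merged.

    Quadratic in sequence length; mirrors only the definition: a stretch of
    at least ``min_total_len`` bp (and two full units) where each base equals
    the base one unit earlier, for some unit length <= ``max_unit``.
    """
    n = len(seq)
    ivs = []
    for u in range(min_unit, max_unit + 1):
        for a in range(n):
            if seq[a] == "N":
                continue
            b = a + u
            while b < n and seq[b] == seq[b - u] and seq[b] != "N":
                b += 1
            if b - a >= max(min_total_len, 2 * u):
                ivs.append((a, b))
    if not ivs:
        return []
    ivs.sort()
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]
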