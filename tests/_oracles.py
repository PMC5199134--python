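"""Independent brute-force oracles the fast implementations are checked against.

Everything here is deliberately naive pure-Python: per-feature loops,
all-pairs scans.  Nothing imports the engine's evaluation code.
"""

TOL = 1e-9
LEVEL_ORDER = ["None", "Low", "Medium", "High"]


def brute_force_panel(percentages, defined, panel_enabled, intervals):
    """Feature ids passing one panel, by a per-feature per-constraint loop.

    percentages: dict feature -> dict facet -> pct
    defined:     dict feature -> bool
    intervals:   dict facet -> (min, max)
    """
    features = list(percentages)
    if not panel_enabled:
        return features
    active = {f: iv for f, iv in intervals.items() if iv != (0.0, 100.0)}
    if not active:
        return features
    out = []
    for feat in features:
        if not defined[feat]:
            continue
        ok = True
        for facet, (lo, hi) in active.items():
            p = percentages[feat][facet]
            if not (lo - TOL <= p <= hi + TOL):
                ok = False
                break
        if ok:
            out.append(feat)
    return out


def brute_force_select(percentages, defined, panels, combiner):
    """Multi-panel selection oracle over a shared feature universe.

    panels: list of (enabled, intervals) evaluated on the same
    percentages table (single-universe case, which is what the random
    equivalence tests generate).
    """
    features = list(percentages)
    enabled = [(en, iv) for en, iv in panels if en]
    if not enabled:
        return features
    per_panel = [
        set(brute_force_panel(percentages, defined, True, iv)) for _, iv in enabled
    ]
    if combiner == "AND":
        keep = set(features)
        for s in per_panel:
            keep &= s
    else:
        keep = set()
        for s in per_panel:
            keep |= s
    return [f for f in features if f in keep]


def brute_force_snp_pairs(enhancers, snps, max_dist):
    """All-pairs midpoint-distance scan.

    enhancers: list of (id, chrom, start, end); snps: list of (id, chrom, pos).
    """
    pairs = set()
    for eid, echrom, start, end in enhancers:
        mid = (start + end) // 2
        for sid, schrom, pos in snps:
            if echrom == schrom and abs(mid - pos) <= max_dist:
                pairs.add((eid, sid))
    return pairs


def brute_force_window(features, tss_list, chrom, window, anchor="midpoint"):
    """All-features scan for the gene-window filter (union over TSSs)."""
    out = []
    for fid, fchrom, start, end, strand in features:
        if anchor == "midpoint":
            point = (start + end) // 2
        else:
            point = start if strand != "-" else end - 1
        if fchrom == chrom and any(t - window <= point <= t + window for t in tss_list):
            out.append(fid)
    return out
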