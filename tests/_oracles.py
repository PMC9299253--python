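"""Independent brute-force reference implementations used as oracles.

Everything here is written with plain per-site loops and dictionaries,
deliberately sharing no code path with the package's vectorized
implementations.
"""

from __future__ import annotations

import numpy as np

NUCS = ("A", "T", "C", "G")


# -- ascertainment ----------------------------------------------------------


def oracle_indseq_keep(table, ref_labels, maf_min, depth_max_cum, depth_min_each):
    """Set of (chrom, pos) surviving the count-based indseq filters."""
    keep = set()
    ref_idx = [table.samples.index(s) for s in ref_labels]
    for i in range(table.n_sites):
        nuc = [0, 0, 0, 0]
        cum = 0
        for j in ref_idx:
            for k in range(4):
                nuc[k] += int(table.counts[i, j, k])
            cum += int(table.counts[i, j].sum())
        tot = sum(nuc)
        maf = 1 - max(nuc) / tot if tot > 0 else 0.0
        if maf < maf_min or cum > depth_max_cum:
            continue
        if any(int(table.counts[i, j].sum()) < depth_min_each
               for j in range(len(table.samples))):
            continue
        keep.add((table.chrom[i], int(table.pos[i])))
    return keep


def oracle_poolseq_keep(table, pool_a, pool_b, maf_min, depth_lo, depth_hi,
                        depth_min_pool):
    keep = set()
    ia, ib = table.samples.index(pool_a), table.samples.index(pool_b)
    for i in range(table.n_sites):
        da = int(table.counts[i, ia].sum())
        db = int(table.counts[i, ib].sum())
        nuc = [int(table.counts[i, ia, k]) + int(table.counts[i, ib, k])
               for k in range(4)]
        tot = sum(nuc)
        maf = 1 - max(nuc) / tot if tot > 0 else 0.0
        if (depth_lo <= da + db <= depth_hi and maf >= maf_min
                and da >= depth_min_pool and db >= depth_min_pool):
            keep.add((table.chrom[i], int(table.pos[i])))
    return keep


def oracle_spacing_keep(sites_list, spacing_min_bp):
    """sites_list: list of (chrom, pos).  Mutual removal: a site survives iff
    no other site on the same chromosome lies closer than the threshold."""
    keep = set()
    for c, p in sites_list:
        ok = True
        for c2, p2 in sites_list:
            if (c2, p2) != (c, p) and c2 == c and abs(p2 - p) < spacing_min_bp:
                ok = False
        if ok:
            keep.add((c, p))
    return keep


# -- window scan ------------------------------------------------------------


def oracle_window_scan(chrom, pos, values, window_bp, step_bp, min_snps):
    """List of (chrom, start, end, mean, n) per brute-force assignment."""
    out = []
    for c in dict.fromkeys(chrom):  # preserve order
        ps = [(p, v) for cc, p, v in zip(chrom, pos, values) if cc == c]
        if not ps:
            continue
        max_pos = max(p for p, _ in ps)
        start = 1
        while start <= max_pos:
            end = start + window_bp - 1
            inside = [v for p, v in ps if start <= p <= end]
            if len(inside) >= min_snps:
                out.append((c, start, end, sum(inside) / len(inside), len(inside)))
            start += step_bp
    return out


# -- statistics -------------------------------------------------------------


def oracle_afd(fa, fb):
    return 0.5 * sum(abs(x - y) for x, y in zip(fa, fb))


def oracle_nei_fst(fa, fb):
    hs = 1 - (sum(x * x for x in fa) + sum(x * x for x in fb)) / 2
    pbar = [(x + y) / 2 for x, y in zip(fa, fb)]
    ht = 1 - sum(x * x for x in pbar)
    return 0.0 if ht <= 0 else (ht - hs) / ht


# -- panel selection --------------------------------------------------------


def oracle_greedy_panel(cands, spacing_min_bp):
    """cands: list of (afd, chrom, pos).  Greedy acceptance in descending
    AFD (ties by coordinate); returns set of (chrom, pos)."""
    order = sorted(cands, key=lambda t: (-t[0], t[1], t[2]))
    accepted = []
    for a, c, p in order:
        if all(c != c2 or abs(p - p2) >= spacing_min_bp for c2, p2 in accepted):
            accepted.append((c, p))
    return set(accepted)


def all_admissible_subsets(cands, spacing_min_bp):
    """Every subset of candidate (chrom, pos) sites that satisfies the
    pairwise spacing constraint (for tiny instances only)."""
    from itertools import combinations

    sites = [(c, p) for _, c, p in cands]
    out = []
    for r in range(len(sites) + 1):
        for comb in combinations(sites, r):
            ok = all(
                c1 != c2 or abs(p1 - p2) >= spacing_min_bp
                for (c1, p1), (c2, p2) in combinations(comb, 2)
            )
            if ok:
                out.append(set(comb))
    return out


# -- neutral filter ---------------------------------------------------------


def oracle_neutral_keep(sites_list, afd_mf, afd_ab, lengths, threshold, peripheral):
    keep = set()
    for (c, p), mf, ab in zip(sites_list, afd_mf, afd_ab):
        both_high = (not np.isnan(mf) and mf > threshold
                     and not np.isnan(ab) and ab > threshold)
        is_peripheral = p <= peripheral or p > lengths[c] - peripheral
        if not both_high and is_peripheral:
            keep.add((c, p))
    return keep


# -- window genotyping ------------------------------------------------------


def oracle_window_genotype(table, individuals, chrom, center, width, depth_min,
                           het_maf, max_ind_missing, max_snp_missing, maf_min):
    """Returns (kept individual labels, kept positions, {(lab,pos): genotype})."""
    half = width // 2
    lo, hi = center - half, center + width - half - 1
    pos_list = [int(p) for c, p in zip(table.chrom, table.pos)
                if c == chrom and lo <= p <= hi]
    calls = {}
    for lab in individuals:
        j = table.samples.index(lab)
        for p in pos_list:
            i = [k for k in range(table.n_sites)
                 if table.chrom[k] == chrom and int(table.pos[k]) == p][0]
            total = int(table.counts[i, j].sum())
            nuc = [int(x) for x in table.counts[i, j, :4]]
            if total < depth_min or sum(nuc) == 0:
                calls[(lab, p)] = "??"
                continue
            ranked = sorted(range(4), key=lambda k: (-nuc[k], k))
            maf = 1 - nuc[ranked[0]] / sum(nuc)
            if maf > het_maf:
                pair = sorted([NUCS[ranked[0]], NUCS[ranked[1]]])
                calls[(lab, p)] = pair[0] + pair[1]
            else:
                calls[(lab, p)] = NUCS[ranked[0]] * 2
    kept_ind = []
    for lab in individuals:
        miss = sum(calls[(lab, p)] == "??" for p in pos_list) / len(pos_list)
        if miss <= max_ind_missing:
            kept_ind.append(lab)
    kept_pos = []
    for p in pos_list:
        col = [calls[(lab, p)] for lab in kept_ind]
        called = [g for g in col if g != "??"]
        miss = 1 - len(called) / len(col) if col else 1.0
        if miss > max_snp_missing or not called:
            continue
        alleles = "".join(called)
        counts = {}
        for a in alleles:
            counts[a] = counts.get(a, 0) + 1
        maf = 1 - max(counts.values()) / len(alleles)
        if maf >= maf_min:
            kept_pos.append(p)
    return kept_ind, kept_pos, calls


# -- neighbour joining ------------------------------------------------------


def oracle_nj(labels, dist):
    """Textbook neighbour joining; returns the tree as nested tuples of
    labels (topology only)."""
    nodes = list(labels)
    d = {(a, b): dist[i][j] for i, a in enumerate(labels) for j, b in enumerate(labels)}

    def dd(a, b):
        return 0.0 if a == b else d[(a, b)]

    while len(nodes) > 2:
        n = len(nodes)
        r = {a: sum(dd(a, b) for b in nodes) for a in nodes}
        best, bi, bj = None, None, None
        for i in range(n):
            for j in range(i + 1, n):
                a, b = nodes[i], nodes[j]
                q = (n - 2) * dd(a, b) - r[a] - r[b]
                if best is None or q < best:
                    best, bi, bj = q, a, b
        new = (bi, bj)
        for c in nodes:
            if c in (bi, bj):
                continue
            v = 0.5 * (dd(bi, c) + dd(bj, c) - dd(bi, bj))
            d[(new, c)] = d[(c, new)] = v
        nodes = [c for c in nodes if c not in (bi, bj)] + [new]
    return tuple(nodes)


def cherries(tree):
    """Set of frozenset label pairs that are sisters in a nested-tuple tree."""
    out = set()

    def walk(t):
        if isinstance(t, tuple):
            if all(not isinstance(x, tuple) for x in t) and len(t) == 2:
                out.add(frozenset(t))
            for x in t:
                walk(x)

    walk(tree)
    return out


# -- random instances -------------------------------------------------------


def random_count_table(rng, n_sites=60, n_samples=4, chroms=("chrI", "chrII"),
                       max_count=40, zero_prob=0.1, span=5_000):
    """A random small CountTable (importable without the package under test
    only via its constructor)."""
    from sgvscan.io import CountTable

    per = rng.multinomial(n_sites, np.full(len(chroms), 1 / len(chroms)))
    chrom_col, pos_col = [], []
    for c, k in zip(chroms, per):
        pos = np.sort(rng.choice(np.arange(1, span), size=k, replace=False))
        chrom_col += [c] * k
        pos_col += pos.tolist()
    counts = rng.integers(0, max_count, size=(n_sites, n_samples, 6))
    counts[:, :, 4:] = rng.integers(0, 3, size=(n_sites, n_samples, 2))
    mask = rng.random(size=(n_sites, n_samples, 6)) < zero_prob
    counts[mask] = 0
    samples = [f"s{i}" for i in range(n_samples)]
    return CountTable(
        samples=samples,
        chrom=np.asarray(chrom_col, dtype=object),
        pos=np.asarray(pos_col, dtype=np.int64),
        ref=np.asarray(rng.choice(list(NUCS), size=n_sites), dtype=object),
        counts=counts,
    )
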