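"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity by direct enumeration or pattern
sliding, sharing no code path with the implementation it checks (beyond
the pattern definitions, which are part of the contract under test).
"""

import itertools

import numpy as np
from scipy import stats

from mirsnp.seeds import SITE_LENGTHS, SITE_PRIORITY, TargetSite, seed_match_site


def brute_force_scan(window, catalog):
    """Slide every counted pattern over every offset; apply the priority rule.

    The locus of a site is the start of its seed-2-7 core hexamer, so the
    nested variants of one seed occurrence compete for a single report.
    """
    best = {}  # (mirna_name, locus) -> (priority_rank, site_type, start)
    for mirna in catalog.records:
        patterns = seed_match_site(mirna)
        for site_type in SITE_PRIORITY:
            if site_type not in catalog.counted_types:
                continue
            pattern = patterns[site_type]
            length = SITE_LENGTHS[site_type]
            for start in range(len(window) - length + 1):
                if window[start : start + length] != pattern:
                    continue
                locus = start + 1 if site_type in ("7mer-m8", "8mer-1a") else start
                rank = SITE_PRIORITY.index(site_type)
                key = (mirna.name, locus)
                if key not in best or rank < best[key][0]:
                    best[key] = (rank, site_type, start)
    sites = [
        TargetSite(name, site_type, start, start + SITE_LENGTHS[site_type])
        for (name, _), (_, site_type, start) in best.items()
    ]
    sites.sort(key=lambda s: (s.start, s.mirna_name, s.site_type))
    return sites


def fisher_two_sided_enumeration(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration (prob-mass rule)."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    pmf = stats.hypergeom(n, row1, col1).pmf
    p_obs = pmf(a)
    total = 0.0
    for x in range(max(0, col1 - (c + d)), min(row1, col1) + 1):
        px = pmf(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


def rank_sum_exact_two_sided(xs, ys):
    """Two-sided rank-sum p by enumerating every split of the combined ranks."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    n1, n = len(xs), len(xs) + len(ys)
    ranks = stats.rankdata(np.concatenate([xs, ys]))
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mean = n1 * len(ys) / 2
    hits = 0
    count = 0
    for comb in itertools.combinations(range(n), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        hits += abs(u - mean) >= abs(u_obs - mean) - 1e-9
        count += 1
    return hits / count


def spearman_exact_two_sided(g, e):
    """Exact two-sided Spearman p: enumerate every pairing, computing the
    statistic with scipy.stats.spearmanr each time."""
    g = np.asarray(g, float)
    e = np.asarray(e, float)
    rho_obs = abs(stats.spearmanr(g, e).statistic)
    hits = 0
    count = 0
    for perm in itertools.permutations(e):
        rho = stats.spearmanr(g, np.asarray(perm)).statistic
        hits += abs(rho) >= rho_obs - 1e-12
        count += 1
    return hits / count


def random_catalog(rng, n_mirnas, counted_types):
    """Small random catalog for oracle-equivalence sweeps."""
    from mirsnp.seeds import MiRNARecord, SeedCatalog

    bases = np.array(list("ACGT"))
    records = []
    seen = set()
    while len(records) < n_mirnas:
        seq = "".join(rng.choice(bases, size=20))
        if seq[1:8] in seen:
            continue
        seen.add(seq[1:8])
        records.append(MiRNARecord(f"m{len(records)}", seq))
    return SeedCatalog(tuple(records), frozenset(counted_types))


def random_window(rng, min_len=6, max_len=60, n_frac=0.05):
    length = int(rng.integers(min_len, max_len + 1))
    alphabet = np.array(list("ACGTN"))
    probs = np.array([1, 1, 1, 1, 0.0]) / 4
    probs = probs * (1 - n_frac)
    probs[4] = n_frac
    return "".join(rng.choice(alphabet, size=length, p=probs))
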