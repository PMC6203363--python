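"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by enumeration or direct scanning,
sharing only the energy-model *parameters* with the implementation —
never its algorithms.
"""

from functools import lru_cache

from mircompare.seqio import revcomp


def enumerate_structures(seq: str, min_loop: int = 3):
    """Every pseudoknot-free pair set over the canonical RNA pairs."""
    seq = seq.upper().replace("T", "U")
    n = len(seq)
    pairable = {"AU", "UA", "GC", "CG", "GU", "UG"}

    @lru_cache(maxsize=None)
    def rec(i: int, j: int):
        if j - i < min_loop + 1:
            return (frozenset(),)
        out = list(rec(i + 1, j))
        for k in range(i + min_loop + 1, j + 1):
            if seq[i] + seq[k] in pairable:
                for a in rec(i + 1, k - 1):
                    for b in rec(k + 1, j):
                        out.append(a | b | {(i, k)})
        return tuple(out)

    return rec(0, n - 1)


def score_structure(seq: str, pairs, model) -> float:
    """Independent loop-decomposition scorer (recursive descent)."""
    seq = seq.upper().replace("T", "U")
    plist = sorted(pairs)

    def direct_children(i, j, pool):
        kids = []
        cursor = i + 1
        for p in pool:
            if p[0] >= cursor and p[1] <= j:
                if not kids or p[0] > kids[-1][1]:
                    kids.append(p)
                    cursor = p[1]
        return kids

    def loop_energy(i, j, inside):
        kids = direct_children(i, j, inside)
        if not kids:
            return model.hairpin_loop_penalty(j - i - 1)
        total = 0.0
        for (k, l) in kids:
            sub = [p for p in inside if k <= p[0] and p[1] <= l and p != (k, l)]
            total += loop_energy(k, l, sub)
        if len(kids) == 1:
            (k, l) = kids[0]
            l1, l2 = k - i - 1, j - l - 1
            if l1 == 0 and l2 == 0:
                return total + model.stack(seq[i] + seq[j], seq[k] + seq[l])
            if l1 == 0 or l2 == 0:
                return total + model.bulge_penalty(l1 + l2)
            return total + model.internal_loop_penalty(l1 + l2)
        return total + model.multiloop_init + model.multiloop_branch * (1 + len(kids))

    top = direct_children(-1, len(seq), plist)
    total = 0.0
    for (i, j) in top:
        sub = [p for p in plist if i <= p[0] and p[1] <= j and p != (i, j)]
        total += loop_energy(i, j, sub)
    return total


def brute_force_mfe(seq: str, model) -> float:
    best = 0.0
    for s in enumerate_structures(seq, model.min_loop):
        if s:
            best = min(best, score_structure(seq, tuple(sorted(s)), model))
    return best


def naive_exact_scan(mature: str, chrom_id: str, chrom_seq: str):
    """All exact full-length occurrences on both strands, O(n*m)."""
    hits = []
    m = len(mature)
    rc = revcomp(mature)
    for p in range(len(chrom_seq) - m + 1):
        window = chrom_seq[p : p + m]
        if window == mature:
            hits.append((chrom_id, "+", p, p + m))
        if window == rc:
            hits.append((chrom_id, "-", p, p + m))
    return hits


def brute_force_sites(mature: str, utr_id: str, utr_seq: str):
    """Check all four site-class definitions at every UTR offset."""
    from mircompare.targets import seed_heptamer

    hept = seed_heptamer(mature)
    core = revcomp(hept[:6])
    m8 = revcomp(hept)  # 7 nt, complement of pos 8 first
    found = []
    n = len(utr_seq)
    for p in range(n - 5):
        if utr_seq[p : p + 6] != core:
            continue
        has_m8 = p >= 1 and utr_seq[p - 1 : p + 6] == m8
        has_a1 = p + 6 < n and utr_seq[p + 6] == "A"
        if has_m8 and has_a1:
            found.append((utr_id, "8mer", p - 1, p + 7))
        elif has_m8:
            found.append((utr_id, "7mer-m8", p - 1, p + 6))
        elif has_a1:
            found.append((utr_id, "7mer-A1", p, p + 7))
        else:
            found.append((utr_id, "6mer", p, p + 6))
    return found
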