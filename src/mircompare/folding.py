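"""Hairpin folding and the MFE/AMFE/MFEI acceptance gate.

The secondary-structure model is a frozen nearest-neighbor model:
Watson-Crick and GU wobble pairs, stacking energies for adjacent pairs,
tabulated hairpin/bulge/internal-loop penalties with logarithmic
extrapolation beyond the table, and a simple affine multiloop penalty.
The minimum-free-energy structure over all pseudoknot-free foldings is
found by Zuker-style dynamic programming; the all-unpaired structure has
energy zero, so the MFE is never positive.

Candidate precursors are accepted when they form a single stem-loop of
52-148 nt whose MFEI = (MFE / length * 100) / GC% is at or below -0.85
and whose mature product sits fully on one arm, mostly base-paired.
Multibranched folds are still scored (so they can be rejected as "not a
single hairpin") but are never accepted as precursors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from ._fold_kernel import INF, fill_tables
from .seqio import dna_to_rna

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
_PAIR_NAMES = ("AU", "CG", "GC", "UA", "GU", "UG")
_PAIR_INDEX = {p: i for i, p in enumerate(_PAIR_NAMES)}

# Thermal factor for Jacobson-Stockmayer loop extrapolation, kcal/mol at 37C
_RT = 0.616
_LOOP_EXTRAP = 1.75 * _RT

MIN_FOLD_LEN = 12
MAX_FOLD_LEN = 200


def _reverse_pair(p: str) -> str:
    return p[1] + p[0]


def _default_stack_table() -> dict[tuple[str, str], float]:
    # outer pair (5' side i, 3' side j) stacked on inner pair (i+1, j-1);
    # kcal/mol; satisfies the helix rotation identity
    # E(p/q) = E(rev(q)/rev(p)) exactly.
    # GU-involving stacks are capped at -0.7 kcal/mol: wobble-rich helices
    # are what lets random low-GC sequence imitate a precursor stem
    rows = {
        "AU": {"AU": -0.9, "CG": -2.2, "GC": -2.1, "UA": -1.1, "GU": -0.6, "UG": -0.7},
        "CG": {"AU": -2.1, "CG": -3.3, "GC": -2.4, "UA": -2.1, "GU": -0.7, "UG": -0.7},
        "GC": {"AU": -2.4, "CG": -3.4, "GC": -3.3, "UA": -2.2, "GU": -0.7, "UG": -0.7},
        "UA": {"AU": -1.3, "CG": -2.4, "GC": -2.1, "UA": -0.9, "GU": -0.7, "UG": -0.7},
        "GU": {"AU": -0.7, "CG": -0.7, "GC": -0.7, "UA": -0.7, "GU": -0.5, "UG": -0.6},
        "UG": {"AU": -0.7, "CG": -0.7, "GC": -0.7, "UA": -0.6, "GU": -0.3, "UG": -0.5},
    }
    table = {(p, q): e for p, qs in rows.items() for q, e in qs.items()}
    for (p, q), e in table.items():
        assert table[(_reverse_pair(q), _reverse_pair(p))] == e
    return table


def _extrapolated(tab: dict[int, float], n: int, base: int) -> float:
    return tab[base] + _LOOP_EXTRAP * math.log(n / base)


@dataclass(frozen=True, eq=False)  # identity hash: instances cache their arrays
class EnergyModel:
    """Frozen nearest-neighbor energy parameters (kcal/mol)."""

    stack_energy: dict[tuple[str, str], float] = field(
        default_factory=_default_stack_table
    )
    hairpin_tab: dict[int, float] = field(
        default_factory=lambda: {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
    )
    bulge_tab: dict[int, float] = field(
        default_factory=lambda: {1: 4.8, 2: 3.8, 3: 4.2, 4: 4.6, 5: 5.0, 6: 5.4}
    )
    internal_tab: dict[int, float] = field(
        default_factory=lambda: {2: 3.0, 3: 3.3, 4: 3.5, 5: 3.7, 6: 3.8, 7: 3.9, 8: 4.0, 9: 4.1}
    )
    multiloop_init: float = 3.4
    multiloop_branch: float = 0.4
    min_loop: int = 3
    max_interior: int = 30

    def hairpin_loop_penalty(self, size: int) -> float:
        if size < self.min_loop:
            return INF
        if size in self.hairpin_tab:
            return self.hairpin_tab[size]
        return _extrapolated(self.hairpin_tab, size, max(self.hairpin_tab))

    def bulge_penalty(self, size: int) -> float:
        if size in self.bulge_tab:
            return self.bulge_tab[size]
        return _extrapolated(self.bulge_tab, size, max(self.bulge_tab))

    def internal_loop_penalty(self, size: int) -> float:
        if size in self.internal_tab:
            return self.internal_tab[size]
        return _extrapolated(self.internal_tab, size, max(self.internal_tab))

    def pairable(self, a: str, b: str) -> bool:
        return (a + b) in _PAIR_INDEX

    def stack(self, outer: str, inner: str) -> float:
        return self.stack_energy[(outer, inner)]

    def _arrays(self, maxlen: int = MAX_FOLD_LEN + 1):
        return _model_arrays(self, maxlen)


@lru_cache(maxsize=4)
def _model_arrays(model: EnergyModel, maxlen: int):
    pt = np.full((4, 4), -1, dtype=np.int64)
    for p, idx in _PAIR_INDEX.items():
        pt[_BASE_CODE[p[0]], _BASE_CODE[p[1]]] = idx
    stack = np.zeros((6, 6))
    for i, p in enumerate(_PAIR_NAMES):
        for j, q in enumerate(_PAIR_NAMES):
            stack[i, j] = model.stack_energy.get((p, q), 0.0)
    hp = np.array([model.hairpin_loop_penalty(s) if s >= model.min_loop else INF
                   for s in range(maxlen)])
    bu = np.array([model.bulge_penalty(s) if s >= 1 else INF for s in range(maxlen)])
    il = np.array([model.internal_loop_penalty(s) if s >= 2 else INF
                   for s in range(maxlen)])
    return pt, stack, hp, bu, il


DEFAULT_MODEL = EnergyModel()


@dataclass
class HairpinStructure:
    """An MFE fold plus the derived hairpin statistics."""

    sequence: str  # RNA alphabet
    dot_bracket: str
    mfe: float  # kcal/mol, <= 0
    amfe: float  # MFE per 100 nt
    mfei: float  # AMFE / GC%
    gc_percent: float  # 0-100 scale
    pairs: tuple[tuple[int, int], ...]
    n_hairpin_loops: int
    loop: tuple[int, int] | None  # terminal loop of the maximal stem, half-open
    stem_span: tuple[int, int] | None  # outermost pair of the maximal stem, half-open
    components: tuple["StemComponent", ...] = ()
    mature_arm: str | None = None  # '5p' | '3p' | 'spans-loop' | 'none'
    paired_mature_fraction: float | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


def gc_percent(seq: str) -> float:
    if not seq:
        return 0.0
    return 100.0 * sum(1 for c in seq.upper() if c in "GCgc") / len(seq)


def mfei(mfe: float, length: int, gc_pct: float) -> tuple[float, float]:
    """AMFE = MFE/length*100; MFEI = AMFE / GC% (GC on the 0-100 scale).

    A GC-free sequence has no defined MFEI (returned as NaN, which no
    threshold test ever passes).
    """
    if length <= 0:
        raise ValueError("length must be positive")
    amfe = mfe / length * 100.0
    if gc_pct <= 0:
        return amfe, float("nan")
    return amfe, amfe / gc_pct


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_CODE[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"cannot fold sequence containing {exc.args[0]!r}") from exc


def structure_energy(sequence: str, pairs, model: EnergyModel = DEFAULT_MODEL) -> float:
    """Score an explicit pseudoknot-free pair set under the model.

    Used to verify tracebacks and to rescore trimmed precursors; the
    decomposition (hairpin / stack / bulge / internal / multiloop, exterior
    free) matches the DP recursion exactly.
    """
    seq = dna_to_rna(sequence.upper())
    plist = sorted(pairs)
    for a, b in plist:
        if not model.pairable(seq[a], seq[b]):
            raise ValueError(f"unpairable bases at ({a},{b})")
    # children of each pair under nesting
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in plist}
    stack_: list[tuple[int, int]] = []
    top: list[tuple[int, int]] = []
    for p in plist:
        while stack_ and not (stack_[-1][0] < p[0] and p[1] < stack_[-1][1]):
            stack_.pop()
        if stack_:
            children[stack_[-1]].append(p)
        else:
            top.append(p)
        stack_.append(p)
    total = 0.0
    for (i, j), cs in children.items():
        if not cs:
            total += model.hairpin_loop_penalty(j - i - 1)
        elif len(cs) == 1:
            (k, l) = cs[0]
            l1, l2 = k - i - 1, j - l - 1
            if l1 == 0 and l2 == 0:
                total += model.stack(seq[i] + seq[j], seq[k] + seq[l])
            elif l1 == 0 or l2 == 0:
                total += model.bulge_penalty(l1 + l2)
            else:
                total += model.internal_loop_penalty(l1 + l2)
        else:
            total += model.multiloop_init + model.multiloop_branch * (1 + len(cs))
    return total


_TOL = 1e-6


def _trace_V(i, j, V, M, codes, pt, stack, hp, bu, il, model, pairs):
    pairs.append((i, j))
    target = V[i, j]
    if abs(hp[j - i - 1] - target) < _TOL:
        return
    p_ij = pt[codes[i], codes[j]]
    kmax = min(i + model.max_interior + 1, j - model.min_loop - 1)
    for k in range(i + 1, kmax + 1):
        l1 = k - i - 1
        for l in range(j - 1, max(k + model.min_loop, j - 2 - (model.max_interior - l1)), -1):
            if V[k, l] >= INF:
                continue
            l2 = j - l - 1
            if l1 == 0 and l2 == 0:
                e = stack[p_ij, pt[codes[k], codes[l]]]
            elif l1 == 0 or l2 == 0:
                e = bu[l1 + l2]
            else:
                e = il[l1 + l2]
            if abs(V[k, l] + e - target) < _TOL:
                _trace_V(k, l, V, M, codes, pt, stack, hp, bu, il, model, pairs)
                return
    base = model.multiloop_init + model.multiloop_branch
    for k in range(i + 2, j - 1):
        if M[i + 1, k] < INF and M[k + 1, j - 1] < INF:
            if abs(base + M[i + 1, k] + M[k + 1, j - 1] - target) < _TOL:
                _trace_M(i + 1, k, V, M, codes, pt, stack, hp, bu, il, model, pairs)
                _trace_M(k + 1, j - 1, V, M, codes, pt, stack, hp, bu, il, model, pairs)
                return
    raise AssertionError("traceback failed in V")  # pragma: no cover


def _trace_M(i, j, V, M, codes, pt, stack, hp, bu, il, model, pairs):
    target = M[i, j]
    if V[i, j] < INF and abs(V[i, j] + model.multiloop_branch - target) < _TOL:
        _trace_V(i, j, V, M, codes, pt, stack, hp, bu, il, model, pairs)
        return
    if abs(M[i + 1, j] - target) < _TOL:
        _trace_M(i + 1, j, V, M, codes, pt, stack, hp, bu, il, model, pairs)
        return
    if abs(M[i, j - 1] - target) < _TOL:
        _trace_M(i, j - 1, V, M, codes, pt, stack, hp, bu, il, model, pairs)
        return
    for k in range(i + 1, j):
        if M[i, k] < INF and M[k + 1, j] < INF and abs(M[i, k] + M[k + 1, j] - target) < _TOL:
            _trace_M(i, k, V, M, codes, pt, stack, hp, bu, il, model, pairs)
            _trace_M(k + 1, j, V, M, codes, pt, stack, hp, bu, il, model, pairs)
            return
    raise AssertionError("traceback failed in M")  # pragma: no cover


def pairs_to_dotbracket(pairs, n: int) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return "".join(db)


@dataclass(frozen=True)
class StemComponent:
    """One top-level helix component of a fold (a candidate precursor span)."""

    span: tuple[int, int]  # outermost pair, half-open
    pairs: tuple[tuple[int, int], ...]  # all pairs in the subtree
    n_hairpin_loops: int
    terminal_loop: tuple[int, int]  # unpaired interval of the deepest helix


def _nesting(pairs):
    plist = sorted(pairs)
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in plist}
    stack_: list[tuple[int, int]] = []
    top: list[tuple[int, int]] = []
    for p in plist:
        while stack_ and not (stack_[-1][0] < p[0] and p[1] < stack_[-1][1]):
            stack_.pop()
        (children[stack_[-1]] if stack_ else top).append(p)
        stack_.append(p)
    return children, top


def _make_component(t, children) -> StemComponent:
    def subtree(p):
        out = [p]
        for c in children[p]:
            out.extend(subtree(c))
        return out

    def subtree_size(p):
        return 1 + sum(subtree_size(c) for c in children[p])

    sub = subtree(t)
    loops = [p for p in sub if not children[p]]
    node = t
    while children[node]:
        node = max(children[node], key=subtree_size)
    return StemComponent(
        span=(t[0], t[1] + 1),
        pairs=tuple(sorted(sub)),
        n_hairpin_loops=len(loops),
        terminal_loop=(node[0] + 1, node[1]),
    )


def _components(pairs) -> list[StemComponent]:
    children, top = _nesting(pairs)
    return [_make_component(t, children) for t in top]


def candidate_stems(structure: "HairpinStructure") -> tuple[StemComponent, ...]:
    """Every helix of the fold whose subtree is a single stem-loop.

    These are the candidate precursor spans a window offers; nested stems
    appear individually so the acceptance gate can trim a hairpin out of
    an enclosing long-range fold.
    """
    children, _ = _nesting(structure.pairs)
    out = []
    for p in children:
        comp = _make_component(p, children)
        if comp.n_hairpin_loops == 1:
            out.append(comp)
    return tuple(sorted(out, key=lambda c: c.span))


def _stem_statistics(pairs, n):
    """Total hairpin-loop count, plus the maximal stem and its terminal loop."""
    comps = _components(pairs)
    total_loops = sum(c.n_hairpin_loops for c in comps)
    if not comps:
        return total_loops, None, None, ()
    best = max(comps, key=lambda c: (len(c.pairs), -c.span[0]))
    return total_loops, best.terminal_loop, best.span, tuple(comps)


def fold(sequence: str, model: EnergyModel = DEFAULT_MODEL) -> HairpinStructure:
    """MFE fold of a 20-200 nt window (DNA or RNA; N not allowed)."""
    seq_rna = dna_to_rna(sequence.upper())
    n = len(seq_rna)
    if not MIN_FOLD_LEN <= n <= MAX_FOLD_LEN:
        raise ValueError(f"fold length {n} outside [{MIN_FOLD_LEN},{MAX_FOLD_LEN}]")
    if "N" in seq_rna:
        raise ValueError("cannot fold a window containing N")
    codes = _encode(seq_rna)
    pt, stack, hp, bu, il = model._arrays()
    V, M = fill_tables(
        codes, pt, stack, hp, bu, il,
        model.multiloop_init, model.multiloop_branch,
        model.min_loop, model.max_interior,
    )
    # exterior loop: prefix minimisation, unpaired bases free
    W = np.zeros(n + 1)
    choice = np.full(n + 1, -1, dtype=int)
    for j in range(1, n + 1):
        W[j] = W[j - 1]
        for i in range(j - 1):
            if V[i, j - 1] < INF and W[i] + V[i, j - 1] < W[j] - _TOL:
                W[j] = W[i] + V[i, j - 1]
                choice[j] = i
    mfe = float(W[n])
    pairs: list[tuple[int, int]] = []
    j = n
    while j > 0:
        i = choice[j]
        if i < 0:
            j -= 1
        else:
            _trace_V(i, j - 1, V, M, codes, pt, stack, hp, bu, il, model, pairs)
            j = i
    pairs.sort()
    n_loops, loop, span, comps = _stem_statistics(pairs, n)
    gc = gc_percent(seq_rna)
    amfe_v, mfei_v = mfei(mfe, n, gc)
    return HairpinStructure(
        sequence=seq_rna,
        dot_bracket=pairs_to_dotbracket(pairs, n),
        mfe=round(mfe, 6),
        amfe=amfe_v,
        mfei=mfei_v,
        gc_percent=gc,
        pairs=tuple(pairs),
        n_hairpin_loops=n_loops,
        loop=loop,
        stem_span=span,
        components=comps,
    )


def place_mature(structure: HairpinStructure, m_start: int, m_end: int) -> HairpinStructure:
    """Annotate the fold with where the mature sits relative to the terminal loop."""
    if structure.loop is None:
        structure.mature_arm = "none"
        structure.paired_mature_fraction = 0.0
        return structure
    l0, l1 = structure.loop
    if m_end <= l0:
        structure.mature_arm = "5p"
    elif m_start >= l1:
        structure.mature_arm = "3p"
    else:
        structure.mature_arm = "spans-loop"
    paired = {i for p in structure.pairs for i in p}
    width = max(1, m_end - m_start)
    structure.paired_mature_fraction = sum(
        1 for i in range(m_start, m_end) if i in paired
    ) / width
    return structure


@dataclass(frozen=True)
class FoldThresholds:
    mfei_max: float = -0.85
    min_precursor_len: int = 52
    max_precursor_len: int = 148
    paired_mature_min: float = 0.6


@dataclass
class AcceptDecision:
    accepted: bool
    reasons: list[str]
    stem_span: tuple[int, int] | None
    span_mfei: float
    span_amfe: float
    span_gc: float


def _trim_stem(
    structure: HairpinStructure,
    mature_span: tuple[int, int] | None,
    max_len: int,
) -> StemComponent | None:
    """Trim the window to the precursor candidate: the widest single
    stem-loop helix that holds the mature and still fits the length cap.

    Preference order: stems fully containing the mature, then stems within
    the length cap, then wider spans, then left-most.  When the window has
    no single-loop stem near the mature the (multibranched) component
    overlapping it is returned so the gate can report why it fails."""
    stems = candidate_stems(structure)
    comps = structure.components

    def overlap(c: StemComponent) -> int:
        if mature_span is None:
            return 1
        return min(c.span[1], mature_span[1]) - max(c.span[0], mature_span[0])

    def contains(c: StemComponent) -> bool:
        if mature_span is None:
            return True
        return c.span[0] <= mature_span[0] and mature_span[1] <= c.span[1]

    eligible = [c for c in stems if overlap(c) > 0]
    if eligible:
        return max(
            eligible,
            key=lambda c: (
                contains(c),
                c.span[1] - c.span[0] <= max_len,
                c.span[1] - c.span[0],
                -c.span[0],
            ),
        )
    fallback = [c for c in comps if overlap(c) > 0]
    if fallback:
        return max(fallback, key=lambda c: (len(c.pairs), -c.span[0]))
    return None


def accept_hairpin(
    structure: HairpinStructure,
    mature_span: tuple[int, int] | None,
    thresholds: FoldThresholds = FoldThresholds(),
    model: EnergyModel = DEFAULT_MODEL,
    stem: StemComponent | None = None,
) -> AcceptDecision:
    """Apply the precursor gate to the candidate trimmed to its own stem.

    The window is first trimmed to the stem component carrying the mature
    (flanking background may fold into unrelated helices; they are not part
    of the precursor).  The trimmed span must be a single stem-loop of
    52-148 nt with MFEI <= -0.85 — the MFEI computed from the stem's own
    energy, length and GC% — and the mature must sit entirely on one arm,
    mostly base-paired.  All failing rules are reported, not just the first.
    """
    reasons: list[str] = []
    comp = stem if stem is not None else _trim_stem(
        structure, mature_span, thresholds.max_precursor_len
    )
    span_mfei = span_amfe = float("nan")
    span_gc = 0.0
    span = None
    if comp is None:
        reasons.append(
            "no-stem" if not structure.components else "mature-outside-stem"
        )
    else:
        span = comp.span
        s0, s1 = span
        if comp.n_hairpin_loops != 1:
            reasons.append("multi-loop")
        span_len = s1 - s0
        span_gc = gc_percent(structure.sequence[s0:s1])
        span_energy = structure_energy(structure.sequence, comp.pairs, model)
        span_amfe, span_mfei = mfei(span_energy, span_len, span_gc)
        if not (thresholds.min_precursor_len <= span_len <= thresholds.max_precursor_len):
            reasons.append("length")
        if not span_mfei <= thresholds.mfei_max:
            reasons.append("MFEI")
        if mature_span is None:
            reasons.append("no-mature")
        else:
            m0, m1 = mature_span
            l0, l1 = comp.terminal_loop
            if m1 <= l0:
                structure.mature_arm = "5p"
            elif m0 >= l1:
                structure.mature_arm = "3p"
            else:
                structure.mature_arm = "spans-loop"
                reasons.append("spans-loop")
            if m0 < s0 or m1 > s1:
                reasons.append("mature-outside-stem")
            paired = {i for p in comp.pairs for i in p}
            frac = sum(1 for i in range(m0, m1) if i in paired) / max(1, m1 - m0)
            structure.paired_mature_fraction = frac
            if frac < thresholds.paired_mature_min:
                reasons.append("mature-pairing")
    return AcceptDecision(
        accepted=not reasons,
        reasons=reasons,
        stem_span=span,
        span_mfei=span_mfei,
        span_amfe=span_amfe,
        span_gc=span_gc,
    )


@dataclass(frozen=True)
class StabilityReport:
    delta_mfe: float
    delta_mfei: float
    more_stable: str  # 'ref' | 'target' | 'tie'


def compare_ortholog_stability(
    structure_ref: HairpinStructure, structure_target: HairpinStructure,
    tie_tol: float = 0.005,
) -> StabilityReport:
    """Which ortholog folds more stably, judged by the lower (more negative) MFEI."""
    d_mfe = structure_target.mfe - structure_ref.mfe
    d_mfei = structure_target.mfei - structure_ref.mfei
    if abs(d_mfei) < tie_tol:
        side = "tie"
    elif d_mfei > 0:
        side = "ref"
    else:
        side = "target"
    return StabilityReport(d_mfe, d_mfei, side)
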