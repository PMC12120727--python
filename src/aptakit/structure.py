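"""Secondary-structure folding and structure-guided aptamer engineering.

Folding is a weighted maximum-pairing dynamic program (Nussinov-style)
over Watson–Crick plus G·T wobble pairs, with default weights GC=3,
AT=2, GT=1 and a minimum hairpin loop of 3 unpaired bases.  The
downstream design steps need the topology of the fold — where the
helices are and where their internal defects sit — not free energies,
so a maximum-pairing objective is sufficient and exactly testable
against exhaustive enumeration.

From a fold three design products are derived:

* *corrected variants*: for each helix that contains internal
  mismatches, a same-length variant in which each mismatched base is
  replaced by the Watson–Crick complement of the base opposing it, so
  the helix closes;
* *truncations*: contiguous subsequences spanning individual hairpin
  elements (and runs of adjacent elements), the cheap-to-synthesize
  candidates;
* *aptamer–siRNA chimeras*: the aptamer joined to an siRNA sense strand
  through a UU linker with TT overhangs on both strands.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = [
    "FoldParams",
    "FoldResult",
    "Defect",
    "Stem",
    "StemAnnotation",
    "CorrectedVariant",
    "Truncation",
    "VariantSet",
    "ChimeraDesign",
    "fold_mfe",
    "fold_suboptimal",
    "annotate_stems",
    "design_corrected_variants",
    "design_truncations",
    "design_variants",
    "assemble_chimera",
]

_DNA_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_RNA_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


@dataclass(frozen=True)
class FoldParams:
    """Pairing weights and loop constraint for the folding DP.

    ``pair_scores`` maps the unordered pair classes GC/AT/GT to weights;
    ``min_loop`` is the minimum number of unpaired bases a hairpin loop
    must enclose.  Temperature and salt are recorded as metadata only —
    the default engine is not thermodynamic.
    """

    pair_scores: dict[str, float] = field(
        default_factory=lambda: {"GC": 3.0, "AT": 2.0, "GT": 1.0}
    )
    min_loop: int = 3
    temperature_C: float = 25.0
    Na_mM: float = 147.0
    Mg_mM: float = 5.0

    def __post_init__(self) -> None:
        if set(self.pair_scores) != {"GC", "AT", "GT"}:
            raise ValueError("pair_scores must define GC, AT and GT")
        if any(v <= 0 for v in self.pair_scores.values()):
            raise ValueError("pair scores must be positive")
        if self.min_loop < 0:
            raise ValueError("min_loop must be >= 0")

    def score(self, x: str, y: str) -> float:
        """Score of pairing bases x and y, or 0 if they cannot pair."""
        key = "".join(sorted((x, y)))
        if key == "CG":
            return self.pair_scores["GC"]
        if key == "AT":
            return self.pair_scores["AT"]
        if key == "GT":
            return self.pair_scores["GT"]
        return 0.0


DEFAULT_FOLD_PARAMS = FoldParams()


@dataclass(frozen=True)
class FoldResult:
    """A nested pairing of one sequence with its total pairing score."""

    sequence: str
    pairs: frozenset[tuple[int, int]]
    score: float

    @property
    def dot_bracket(self) -> str:
        chars = ["."] * len(self.sequence)
        for i, j in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)

    def partner(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


def _check_dna(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    if not seq or not set(seq) <= set("ACGT"):
        raise ValueError(f"{what} must be a non-empty A/C/G/T string")
    return seq


# ---------------------------------------------------------------------------
# Folding DP
# ---------------------------------------------------------------------------

def _fill_dp(seq: str, params: FoldParams) -> list[list[float]]:
    n = len(seq)
    e = [[0.0] * n for _ in range(n)]
    for span in range(params.min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = e[i + 1][j]
            for k in range(i + params.min_loop + 1, j + 1):
                s = params.score(seq[i], seq[k])
                if s <= 0:
                    continue
                inner = e[i + 1][k - 1] if k - 1 > i else 0.0
                right = e[k + 1][j] if k + 1 <= j else 0.0
                cand = s + inner + right
                if cand > best:
                    best = cand
            e[i][j] = best
    return e


def fold_mfe(seq: str, params: FoldParams = DEFAULT_FOLD_PARAMS) -> FoldResult:
    """Globally optimal nested pairing under the weighted pairing model.

    The traceback is deterministic: where several choices reach the
    optimal score, the left end of the interval is paired in preference
    to being left single-stranded, and with its outermost admissible
    partner — the rule that extends helices outward.
    """
    seq = _check_dna(seq)
    n = len(seq)
    e = _fill_dp(seq, params)
    pairs: set[tuple[int, int]] = set()
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= params.min_loop:
            continue
        target = e[i][j]
        if target == 0:
            continue
        chosen = None
        for k in range(j, i + params.min_loop, -1):  # outermost partner first
            s = params.score(seq[i], seq[k])
            if s <= 0:
                continue
            inner = e[i + 1][k - 1] if k - 1 > i else 0.0
            right = e[k + 1][j] if k + 1 <= j else 0.0
            if s + inner + right == target:
                chosen = k
                break
        if chosen is None:
            stack.append((i + 1, j))
        else:
            pairs.add((i, chosen))
            stack.append((i + 1, chosen - 1))
            stack.append((chosen + 1, j))
    return FoldResult(sequence=seq, pairs=frozenset(pairs), score=e[0][n - 1] if n > 1 else 0.0)


def fold_suboptimal(
    seq: str,
    params: FoldParams = DEFAULT_FOLD_PARAMS,
    n_structures: int = 3,
    margin: float = 0.0,
) -> list[FoldResult]:
    """Up to ``n_structures`` distinct pairings within ``margin`` of the
    optimal score, best first (ties by lexicographic pair list).

    An approximation of a folding server's suboptimal-structure output;
    useful for inspecting alternative helices of a candidate.
    """
    seq = _check_dna(seq)
    n = len(seq)
    e = _fill_dp(seq, params)

    def enum(i: int, j: int, slack: float):
        if i >= j or j - i <= params.min_loop:
            yield frozenset(), 0.0
            return
        target = e[i][j]
        loss_unpaired = target - e[i + 1][j]
        if loss_unpaired <= slack:
            for ps, sc in enum(i + 1, j, slack - loss_unpaired):
                yield ps, sc
        for k in range(i + params.min_loop + 1, j + 1):
            s = params.score(seq[i], seq[k])
            if s <= 0:
                continue
            inner_best = e[i + 1][k - 1] if k - 1 > i else 0.0
            right_best = e[k + 1][j] if k + 1 <= j else 0.0
            loss = target - (s + inner_best + right_best)
            if loss > slack:
                continue
            rem = slack - loss
            for lp, ls in enum(i + 1, k - 1, rem):
                used = inner_best - ls
                for rp, rs in enum(k + 1, j, rem - used):
                    yield frozenset({(i, k)}) | lp | rp, s + ls + rs

    best = e[0][n - 1] if n > 1 else 0.0
    seen: dict[frozenset, float] = {}
    # cap raw enumeration to keep degenerate inputs bounded
    for ps, sc in itertools.islice(enum(0, n - 1, margin), 0, 50_000):
        if ps not in seen:
            seen[ps] = sc
        if len(seen) >= 10 * n_structures and margin == 0:
            break
    ranked = sorted(seen.items(), key=lambda kv: (-kv[1], sorted(kv[0])))
    return [FoldResult(sequence=seq, pairs=ps, score=sc) for ps, sc in ranked[:n_structures]]


# ---------------------------------------------------------------------------
# Stem annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Defect:
    """An internal loop or bulge between two stacked runs of one stem.

    ``five_prime``/``three_prime`` hold the unpaired positions on each
    strand (ascending).  ``opposed()`` pairs them off from the helix
    outward; only opposed positions can be closed by substitution.
    """

    five_prime: tuple[int, ...]
    three_prime: tuple[int, ...]

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(sorted(self.five_prime + self.three_prime))

    def opposed(self) -> list[tuple[int, int]]:
        return list(zip(self.five_prime, sorted(self.three_prime, reverse=True)))


@dataclass(frozen=True)
class Stem:
    """Stacked runs of pairs, possibly interrupted by small defects."""

    pairs: tuple[tuple[int, int], ...]  # outermost -> innermost
    defects: tuple[Defect, ...]

    @property
    def span(self) -> tuple[int, int]:
        return self.pairs[0]

    @property
    def mismatches(self) -> tuple[int, ...]:
        return tuple(sorted(p for d in self.defects for p in d.positions))


@dataclass(frozen=True)
class StemAnnotation:
    stems: tuple[Stem, ...]

    @property
    def mismatches(self) -> tuple[int, ...]:
        return tuple(sorted(p for s in self.stems for p in s.mismatches))


def _stacked_runs(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    runs: list[list[tuple[int, int]]] = []
    for p in sorted(pairs):
        if runs and p[0] == runs[-1][-1][0] + 1 and p[1] == runs[-1][-1][1] - 1:
            runs[-1].append(p)
        else:
            runs.append([p])
    return runs


def annotate_stems(fold: FoldResult, max_defect: int = 2) -> StemAnnotation:
    """Group stacked runs into stems, bridging defects of <= max_defect
    unpaired bases per strand.

    A run merges with the run directly nested inside it when the gap on
    each strand is at most ``max_defect`` bases and the inner run is the
    only element in between (multibranch junctions never merge).  The
    unpaired gap positions are the stem's mismatches.
    """
    runs = _stacked_runs(sorted(fold.pairs))
    if not runs:
        return StemAnnotation(stems=())
    used = [False] * len(runs)
    stems: list[Stem] = []
    for idx, run in enumerate(runs):
        if used[idx]:
            continue
        chain = [run]
        used[idx] = True
        while True:
            a, b = chain[-1][-1]  # innermost pair so far
            nested = [
                jdx
                for jdx, other in enumerate(runs)
                if not used[jdx] and a < other[0][0] and other[0][1] < b
            ]
            direct = [
                jdx
                for jdx in nested
                if not any(
                    runs[kdx][0][0] < runs[jdx][0][0] and runs[jdx][0][1] < runs[kdx][0][1]
                    for kdx in nested
                    if kdx != jdx
                )
            ]
            if len(direct) != 1:
                break
            jdx = direct[0]
            c, d = runs[jdx][0]
            g5, g3 = c - a - 1, b - d - 1
            if max(g5, g3) > max_defect or g5 + g3 == 0:
                break
            chain.append(runs[jdx])
            used[jdx] = True
        pairs = tuple(p for r in chain for p in r)
        defects = []
        for prev, nxt in zip(chain, chain[1:]):
            a, b = prev[-1]
            c, d = nxt[0]
            defects.append(
                Defect(
                    five_prime=tuple(range(a + 1, c)),
                    three_prime=tuple(range(d + 1, b)),
                )
            )
        stems.append(Stem(pairs=pairs, defects=tuple(defects)))
    return StemAnnotation(stems=tuple(sorted(stems, key=lambda s: s.span)))


# ---------------------------------------------------------------------------
# Variant design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrectedVariant:
    name: str
    sequence: str
    parent: str
    stem_span: tuple[int, int]
    substitutions: tuple[tuple[int, str, str], ...]  # (position, old, new)


@dataclass(frozen=True)
class Truncation:
    name: str
    sequence: str
    parent: str
    span: tuple[int, int]  # inclusive 0-based indices into the parent
    elements: tuple[int, ...]


@dataclass(frozen=True)
class VariantSet:
    parent: str
    corrected: tuple[CorrectedVariant, ...]
    truncations: tuple[Truncation, ...]


def design_corrected_variants(
    seq: str,
    fold: FoldResult,
    annotation: StemAnnotation,
    name_prefix: str = "V",
) -> tuple[CorrectedVariant, ...]:
    """One mismatch-corrected variant per defective stem.

    Within a stem, each opposed mismatch has its 3'-side base replaced
    with the Watson–Crick complement of the 5'-side base, closing the
    defect into stacked pairs.  Unopposed bulge bases are untouched (a
    substitution cannot close a bulge without changing length), so stems
    whose only defects are bulges yield no variant.  The parent's length
    is always preserved, and because only unpaired positions change, the
    parent's optimal fold remains feasible: refolding a corrected
    variant can only raise the score.
    """
    seq = _check_dna(seq)
    if fold.sequence != seq:
        raise ValueError("fold was computed for a different sequence")
    variants = []
    counter = 1
    for stem in annotation.stems:
        subs = []
        chars = list(seq)
        for defect in stem.defects:
            for p, q in defect.opposed():
                new = _DNA_COMP[seq[p]]
                if chars[q] != new:
                    subs.append((q, seq[q], new))
                    chars[q] = new
        if subs:
            variants.append(
                CorrectedVariant(
                    name=f"{name_prefix}{counter}",
                    sequence="".join(chars),
                    parent=seq,
                    stem_span=stem.span,
                    substitutions=tuple(subs),
                )
            )
            counter += 1
    return tuple(variants)


def design_truncations(
    seq: str,
    fold: FoldResult,
    name_prefix: str = "T",
    max_combine: int | None = None,
    include_full: bool = True,
) -> tuple[Truncation, ...]:
    """Truncations spanning individual hairpin elements and runs of
    adjacent elements.

    A hairpin element is a top-level helix: an outermost pair together
    with everything nested inside it.  Each element yields the
    contiguous subsequence from its outermost pair's 5' index to its 3'
    index; runs of up to ``max_combine`` adjacent elements (spacer
    included) and, optionally, the full parent are appended.  With two
    hairpins and the defaults this yields the four-variant pattern
    {element 1, element 2, both + spacer, full}.
    """
    seq = _check_dna(seq)
    if fold.sequence != seq:
        raise ValueError("fold was computed for a different sequence")
    outer = sorted(
        (i, j)
        for i, j in fold.pairs
        if not any(a < i and j < b for a, b in fold.pairs)
    )
    if not outer:
        return ()
    spans: list[tuple[tuple[int, int], tuple[int, ...]]] = [
        ((i, j), (idx,)) for idx, (i, j) in enumerate(outer)
    ]
    limit = len(outer) if max_combine is None else max_combine
    for width in range(2, min(limit, len(outer)) + 1):
        for start in range(len(outer) - width + 1):
            i = outer[start][0]
            j = outer[start + width - 1][1]
            spans.append(((i, j), tuple(range(start, start + width))))
    if include_full and (0, len(seq) - 1) not in [s for s, _ in spans]:
        spans.append(((0, len(seq) - 1), tuple(range(len(outer)))))
    out = []
    seen = set()
    for counter, ((i, j), elements) in enumerate(spans, start=1):
        sub = seq[i : j + 1]
        if (i, j) in seen:
            continue
        seen.add((i, j))
        out.append(
            Truncation(
                name=f"{name_prefix}{counter}",
                sequence=sub,
                parent=seq,
                span=(i, j),
                elements=elements,
            )
        )
    return tuple(out)


def design_variants(
    seq: str,
    params: FoldParams = DEFAULT_FOLD_PARAMS,
    max_defect: int = 2,
    name_prefix: str = "V",
    truncation_prefix: str = "T",
) -> VariantSet:
    """Convenience pipeline: fold, annotate, and derive both variant classes."""
    fold = fold_mfe(seq, params)
    annotation = annotate_stems(fold, max_defect=max_defect)
    return VariantSet(
        parent=seq,
        corrected=design_corrected_variants(seq, fold, annotation, name_prefix),
        truncations=design_truncations(seq, fold, name_prefix=truncation_prefix),
    )


# ---------------------------------------------------------------------------
# Aptamer–siRNA chimera assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChimeraDesign:
    """An aptamer–siRNA chimera (AsiC).

    ``assembled_sense_strand`` = aptamer + UU linker + siRNA sense + TT
    overhang; ``assembled_antisense_strand`` = siRNA antisense + TT
    overhang.  ``sense_alphabet`` marks each assembled-sense position as
    DNA ('D') or RNA ('R') — the strands mix alphabets, so T and U are
    never interconverted.
    """

    aptamer: str
    sense: str
    antisense: str
    linker: str = "UU"
    overhang: str = "TT"

    @property
    def assembled_sense_strand(self) -> str:
        return self.aptamer + self.linker + self.sense + self.overhang

    @property
    def assembled_antisense_strand(self) -> str:
        return self.antisense + self.overhang

    @property
    def sense_alphabet(self) -> str:
        return (
            "D" * len(self.aptamer)
            + "R" * len(self.linker)
            + "R" * len(self.sense)
            + "D" * len(self.overhang)
        )


def assemble_chimera(aptamer: str, sense: str, antisense: str) -> ChimeraDesign:
    """Assemble an AsiC, validating that sense and antisense are reverse
    complements over the duplex region (RNA rules)."""
    aptamer = _check_dna(aptamer, "aptamer")
    sense = sense.upper()
    antisense = antisense.upper()
    for name, strand in (("sense", sense), ("antisense", antisense)):
        if not strand or not set(strand) <= set("ACGU"):
            raise ValueError(f"{name} must be a non-empty A/C/G/U RNA string")
    expected = "".join(_RNA_COMP[b] for b in reversed(sense))
    if antisense != expected:
        raise ValueError("antisense is not the reverse complement of sense")
    return ChimeraDesign(aptamer=aptamer, sense=sense, antisense=antisense)
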