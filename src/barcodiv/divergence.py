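"""Barcode divergence statistics between haplogroups.

Two criteria quantify DNA-barcode divergence between groups of aligned
sequences:

1. **Fixed (diagnostic) substitutions** — alignment sites invariant within
   each of two groups but showing different states between them
   (:func:`fixed_substitutions`).
2. **Minimal inter-group uncorrected p-distance** — the two genetically
   closest samples, one from each group, and the proportion of compared
   sites at which they differ, counting both fixed and non-fixed
   substitutions (:func:`min_intergroup`).

Both rest on the elementary uncorrected p-distance (:func:`p_distance`) and
the full pairwise matrix (:func:`distance_matrix`). No multiple-hit
correction is applied anywhere: p is the raw proportion of differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd

from .io import (
    AMBIGUITY_CODES,
    DEFAULT_POLICY,
    Alignment,
    GroupingMap,
    InputError,
    SampleLookupError,
    SitePolicy,
    UndefinedDistanceError,
    warn_singletons,
)

# ---------------------------------------------------------------------------
# Result types

@dataclass(frozen=True)
class PDistance:
    """Uncorrected proportion of differing sites between two sequences."""

    differing_sites: int
    compared_sites: int

    @property
    def value(self) -> float:
        """p as a fraction in [0, 1]."""
        return self.differing_sites / self.compared_sites

    @property
    def percent(self) -> float:
        return 100.0 * self.value

    def render_percent(self) -> str:
        """One-decimal percentage, round-half-up — e.g. ``'2.4 %'``."""
        return render_percent(self.value)


def render_percent(p: float) -> str:
    """Render a fraction as a one-decimal percentage, round-half-up."""
    q = Decimal(repr(100.0 * p)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return f"{q} %"


@dataclass
class DistanceMatrix:
    """All pairwise uncorrected p-distances of an alignment.

    ``entries`` maps each unordered id pair, keyed in ``ids`` order, to its
    :class:`PDistance`; the diagonal is implicitly zero.
    """

    ids: list[str]
    entries: dict[tuple[str, str], PDistance]

    def get(self, a: str, b: str) -> PDistance:
        if a == b:
            raise InputError("diagonal entries are identically zero")
        if (a, b) in self.entries:
            return self.entries[(a, b)]
        if (b, a) in self.entries:
            return self.entries[(b, a)]
        raise SampleLookupError(f"pair ({a!r}, {b!r}) not in matrix")

    def to_dataframe(self) -> pd.DataFrame:
        """Square matrix of p fractions (diagonal zero)."""
        n = len(self.ids)
        arr = np.zeros((n, n))
        index = {sid: i for i, sid in enumerate(self.ids)}
        for (a, b), d in self.entries.items():
            arr[index[a], index[b]] = arr[index[b], index[a]] = d.value
        return pd.DataFrame(arr, index=self.ids, columns=self.ids)

    def to_long(self) -> pd.DataFrame:
        rows = [
            {
                "sample_a": a,
                "sample_b": b,
                "p": d.value,
                "p_percent": d.render_percent(),
                "differing_sites": d.differing_sites,
                "compared_sites": d.compared_sites,
            }
            for (a, b), d in self.entries.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class DiagnosticSiteReport:
    """Sites fixed within and different between two groups.

    ``sites`` lists ``(position, state_a, state_b)`` with 1-based positions
    in strictly increasing order; ``evaluated_sites`` counts sites passing
    the policy mask (at least one unmasked member per group, and not
    dropped by complete deletion).
    """

    group_a: str
    group_b: str
    sites: list[tuple[int, str, str]]
    evaluated_sites: int

    @property
    def count(self) -> int:
        return len(self.sites)


@dataclass
class ClosestPairResult:
    """Minimal inter-group p-distance and the sample pair realizing it."""

    group_a: str
    group_b: str
    pair: tuple[str, str]
    distance: PDistance
    ties: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Residue encoding

_CODES = {res: i + 1 for i, res in enumerate("ACGT")}
_CODES.update({res: i + 5 for i, res in enumerate(sorted(AMBIGUITY_CODES))})
# 0 = masked (gap, N, and — under treat_as_missing — ambiguity codes)


def encode(seq: str, policy: SitePolicy) -> tuple[np.ndarray, np.ndarray]:
    """Encode residues as uint8 codes plus an ``always-mismatch`` flag array.

    Masked residues get code 0. Under ``strict_mismatch``, ambiguity codes
    stay unmasked but are flagged: they never match any state, themselves
    included.
    """
    codes = np.zeros(len(seq), dtype=np.uint8)
    nomatch = np.zeros(len(seq), dtype=bool)
    for i, res in enumerate(seq):
        if policy.masked(res):
            continue
        codes[i] = _CODES[res]
        if res in AMBIGUITY_CODES:
            nomatch[i] = True
    return codes, nomatch


# ---------------------------------------------------------------------------
# Pairwise distance

def p_distance(a: str, b: str, policy: SitePolicy = DEFAULT_POLICY) -> PDistance:
    """Uncorrected p-distance between two equal-length residue strings.

    Sites where either residue is masked under *policy* are excluded from
    ``compared_sites``. With zero comparable sites the distance is
    undefined and raises :class:`UndefinedDistanceError`.
    """
    if len(a) != len(b):
        raise InputError(
            f"sequences have unequal lengths ({len(a)} vs {len(b)})"
        )
    ca, na = encode(a, policy)
    cb, nb = encode(b, policy)
    comparable = (ca != 0) & (cb != 0)
    ncomp = int(comparable.sum())
    if ncomp == 0:
        raise UndefinedDistanceError("no comparable sites between sequences")
    diff = comparable & ((ca != cb) | na | nb)
    return PDistance(differing_sites=int(diff.sum()), compared_sites=ncomp)


def distance_matrix(
    alignment: Alignment, policy: SitePolicy = DEFAULT_POLICY
) -> DistanceMatrix:
    """All pairwise p-distances of *alignment* under *policy*.

    Under ``complete_deletion`` a site masked in any record is dropped for
    every pair; under ``pairwise_deletion`` masking is per pair.
    """
    ids = alignment.ids
    if len(ids) < 2:
        raise InputError("distance matrix needs at least 2 records")
    coded = {sid: encode(alignment[sid], policy) for sid in ids}
    keep = np.ones(alignment.length, dtype=bool)
    if policy.mode == "complete_deletion":
        for codes, _ in coded.values():
            keep &= codes != 0
    entries: dict[tuple[str, str], PDistance] = {}
    for a, b in combinations(ids, 2):
        ca, na = coded[a]
        cb, nb = coded[b]
        comparable = keep & (ca != 0) & (cb != 0)
        ncomp = int(comparable.sum())
        if ncomp == 0:
            raise UndefinedDistanceError(
                f"no comparable sites for pair ({a!r}, {b!r})"
            )
        diff = comparable & ((ca != cb) | na | nb)
        entries[(a, b)] = PDistance(int(diff.sum()), ncomp)
    return DistanceMatrix(ids=ids, entries=entries)


# ---------------------------------------------------------------------------
# Criterion 2: closest inter-group pair

def min_intergroup(
    matrix: DistanceMatrix,
    grouping: GroupingMap,
    group_a: str,
    group_b: str,
) -> ClosestPairResult:
    """Minimal p-distance over all pairs with one member in each group.

    Ties on the minimal distance are broken lexicographically on the
    ``(sample_a, sample_b)`` pair; all tying pairs are reported.
    """
    if group_a == group_b:
        raise InputError("groups must be distinct")
    members_a = [s for s in grouping.members(group_a) if s in matrix.ids]
    members_b = [s for s in grouping.members(group_b) if s in matrix.ids]
    if not members_a or not members_b:
        empty = group_a if not members_a else group_b
        raise SampleLookupError(
            f"group {empty!r} has no members in the distance matrix"
        )
    overlap = set(members_a) & set(members_b)
    if overlap:
        raise InputError(f"groups overlap on samples {sorted(overlap)!r}")
    best: PDistance | None = None
    tying: list[tuple[str, str]] = []
    for sa in members_a:
        for sb in members_b:
            d = matrix.get(sa, sb)
            if best is None or d.value < best.value:
                best, tying = d, [(sa, sb)]
            elif d.value == best.value:
                tying.append((sa, sb))
    tying.sort()
    assert best is not None
    return ClosestPairResult(
        group_a=group_a,
        group_b=group_b,
        pair=tying[0],
        distance=best,
        ties=tying,
    )


# ---------------------------------------------------------------------------
# Criterion 1: fixed (diagnostic) substitutions

def fixed_substitutions(
    alignment: Alignment,
    grouping: GroupingMap,
    group_a: str,
    group_b: str,
    policy: SitePolicy = DEFAULT_POLICY,
) -> DiagnosticSiteReport:
    """Sites invariant within each group but different between the groups.

    A site is diagnostic iff, after masking per *policy*, every unmasked
    member of each group shows one single unambiguous residue, the two
    residues differ, and each group retains at least one unmasked member.
    Sites where a whole group is masked are not evaluable and are excluded
    from ``evaluated_sites``.
    """
    members_a = grouping.members(group_a)
    members_b = grouping.members(group_b)
    if not members_a or not members_b:
        raise InputError("both groups must be non-empty")
    warn_singletons(grouping, (group_a, group_b))
    for sid in members_a + members_b:
        if sid not in alignment:
            raise SampleLookupError(f"grouped sample {sid!r} not in alignment")

    coded_a = [encode(alignment[s], policy) for s in members_a]
    coded_b = [encode(alignment[s], policy) for s in members_b]
    keep = np.ones(alignment.length, dtype=bool)
    if policy.mode == "complete_deletion":
        for codes, _ in coded_a + coded_b:
            keep &= codes != 0

    sites: list[tuple[int, str, str]] = []
    evaluated = 0
    decode = {v: k for k, v in _CODES.items()}
    for pos in range(alignment.length):
        if not keep[pos]:
            continue
        states_a = {c[pos] for c, _ in coded_a if c[pos] != 0}
        states_b = {c[pos] for c, _ in coded_b if c[pos] != 0}
        if not states_a or not states_b:
            continue  # a fully-masked group: site not evaluable
        evaluated += 1
        if len(states_a) != 1 or len(states_b) != 1:
            continue
        sa, sb = states_a.pop(), states_b.pop()
        # an ambiguity code cannot assert a fixed state
        if any(n[pos] for _, n in coded_a) or any(n[pos] for _, n in coded_b):
            continue
        if sa != sb:
            sites.append((pos + 1, decode[sa], decode[sb]))
    return DiagnosticSiteReport(
        group_a=group_a, group_b=group_b, sites=sites, evaluated_sites=evaluated
    )


# ---------------------------------------------------------------------------
# Reporting

def divergence_summary(
    alignment: Alignment,
    grouping: GroupingMap,
    policy: SitePolicy = DEFAULT_POLICY,
) -> pd.DataFrame:
    """Both divergence criteria for every unordered group pair.

    One row per pair, in ``group_order``: fixed-substitution count, minimal
    inter-group p-distance (raw fraction and one-decimal percentage) and
    the closest sample pair. Deterministic on identical input.
    """
    grouping.check_against(alignment)
    labels = [g for g in grouping.group_order if grouping.members(g)]
    if len(labels) < 2:
        raise InputError("divergence summary needs at least 2 groups")
    matrix = distance_matrix(alignment, policy)
    rows = []
    for ga, gb in combinations(labels, 2):
        diag = fixed_substitutions(alignment, grouping, ga, gb, policy)
        closest = min_intergroup(matrix, grouping, ga, gb)
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "fixed_substitutions": diag.count,
                "evaluated_sites": diag.evaluated_sites,
                "min_p": closest.distance.value,
                "min_p_percent": closest.distance.render_percent(),
                "closest_a": closest.pair[0],
                "closest_b": closest.pair[1],
                "differing_sites": closest.distance.differing_sites,
                "compared_sites": closest.distance.compared_sites,
            }
        )
    return pd.DataFrame(rows)
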