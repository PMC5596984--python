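"""Synthetic barcode alignments: a constructive fixture and a JC simulator.

Two generators cover the package's test inputs.

:func:`make_fixture` builds, deterministically, a five-haplogroup COI-like
alignment with *planted* statistics: per-haplogroup diagnostic-site counts,
closest-pair totals, within-group polymorphism, distant outgroup blocks and
a minority of one taxon's samples carrying another haplogroup's haplotype
(mitochondrial introgression). Every planted quantity is recorded in a
truth table so the analysis modules can be checked for exact recovery. The
default configuration mirrors a published *Melitaea persea*-complex
sampling design: an "acentria" taxon of 25 samples split 22/3 between its
own haplogroup A and an introgressed haplogroup P2, a reference haplogroup
P1 of 18, plus P3, H and four outgroup blocks.

:func:`simulate_jc` evolves two lineages from a random root under the
Jukes–Cantor model (per-site Poisson substitution process, each event to a
uniformly chosen different base), optionally with an introgression event,
for stochastic parameter-recovery tests of the clock module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .io import Alignment, GroupingMap, InputError

_BASES = "ACGT"


class ConfigError(InputError):
    """A generator configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# Constructive fixture

@dataclass(frozen=True)
class GroupSpec:
    """Plan for one haplogroup measured against the reference group.

    diagnostic_count
        sites fixed within the group and within the reference but differing
        between them.
    closest_pair_total_differences
        total differing sites between the group's designated closest sample
        and the reference's; must be ≥ diagnostic_count — the excess is
        realised as non-fixed differences.
    polymorphic_sites
        within-group polymorphic sites (one alternative carrier each),
        never touching diagnostic positions.
    """

    label: str
    taxon: str
    n_samples: int
    diagnostic_count: int
    closest_pair_total_differences: int
    polymorphic_sites: int = 2


@dataclass(frozen=True)
class OutgroupSpec:
    """A distant block: all members share one haplotype at ≥6 % divergence."""

    label: str
    taxon: str
    n_samples: int
    divergence_sites: int = 45


@dataclass(frozen=True)
class IntrogressionSpec:
    """Recipient-taxon samples carrying exact donor-haplogroup haplotypes."""

    donor: str
    recipient_taxon: str
    count: int


@dataclass(frozen=True)
class FixtureConfig:
    """Full plan for the constructive fixture; defaults give the
    five-haplogroup, 96-sample design described in the module docstring."""

    length: int = 658
    reference_label: str = "P1"
    reference_taxon: str = "persea"
    reference_n: int = 18
    reference_polymorphic_sites: int = 4
    groups: tuple[GroupSpec, ...] = (
        GroupSpec("P2", "persea", 6, 7, 13, 2),
        GroupSpec("P3", "paphlagonia", 4, 10, 15, 2),
        GroupSpec("A", "acentria", 22, 11, 16, 3),
        GroupSpec("H", "higginsi", 2, 10, 16, 1),
    )
    introgression: IntrogressionSpec | None = IntrogressionSpec(
        donor="P2", recipient_taxon="acentria", count=3
    )
    outgroups: tuple[OutgroupSpec, ...] = (
        OutgroupSpec("casta", "casta", 13),
        OutgroupSpec("didyma", "didyma", 7),
        OutgroupSpec("deserticola", "deserticola", 14),
        OutgroupSpec("trivia", "trivia", 9),
    )

    def validate(self) -> None:
        for g in self.groups:
            if g.diagnostic_count > g.closest_pair_total_differences:
                raise ConfigError(
                    f"group {g.label!r}: diagnostic_count "
                    f"{g.diagnostic_count} exceeds closest-pair total "
                    f"{g.closest_pair_total_differences}"
                )
            if g.n_samples < 1:
                raise ConfigError(f"group {g.label!r}: needs ≥1 sample")
        budget = sum(
            g.closest_pair_total_differences + g.polymorphic_sites
            for g in self.groups
        )
        budget += self.reference_polymorphic_sites
        budget += sum(o.divergence_sites for o in self.outgroups)
        if budget > self.length:
            raise ConfigError(
                f"site budget exceeded: {budget} planted sites > L={self.length}"
            )
        if self.introgression is not None:
            donors = [g.label for g in self.groups]
            if self.introgression.donor not in donors:
                raise ConfigError(
                    f"introgression donor {self.introgression.donor!r} "
                    "is not a configured group"
                )


@dataclass
class FixtureData:
    """A generated fixture: alignment, both groupings and the truth table.

    ``haplogroups`` assigns every sample its (planted) haplogroup — the
    partition the divergence statistics are computed on; ``taxa`` assigns
    the taxon labels a field worker would supply, which disagree with the
    haplogroups exactly for the introgressed samples. ``truth`` records
    every planted quantity.
    """

    alignment: Alignment
    haplogroups: GroupingMap
    taxa: GroupingMap
    truth: dict


def _alt_base(rng: np.random.Generator, *exclude: str) -> str:
    choices = [b for b in _BASES if b not in exclude]
    return choices[rng.integers(len(choices))]


def make_fixture(
    config: FixtureConfig | None = None, seed: int = 1
) -> FixtureData:
    """Deterministically build the planted-statistics fixture.

    Layout: a random reference sequence; consecutive disjoint site blocks
    hold, per haplogroup, its diagnostic sites, then its extra
    (closest-pair) sites, then its polymorphic sites, then the outgroup
    blocks. At a diagnostic site every group member carries one substituted
    base. At an extra site every group member carries a substituted base
    while one reference sample carries a third state — so the site differs
    in every inter-group pair yet is polymorphic in the reference, hence
    not fixed; every group×reference pair therefore differs at exactly
    ``closest_pair_total_differences`` sites (plus any polymorphism carried
    by the specific samples), making the planted total the exact minimum.
    Introgressed samples are byte-exact copies of donor haplotypes.
    """
    config = config or FixtureConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    L = config.length
    ref_seq = [_BASES[i] for i in rng.integers(4, size=L)]

    cursor = 0

    def take(n: int) -> list[int]:
        nonlocal cursor
        block = list(range(cursor, cursor + n))
        cursor += n
        return block

    ref_label = config.reference_label
    ref_members = [f"{ref_label}-{i + 1:02d}" for i in range(config.reference_n)]
    # reference rows start as the base sequence
    rows: dict[str, list[str]] = {sid: list(ref_seq) for sid in ref_members}
    haplo: dict[str, str] = {sid: ref_label for sid in ref_members}
    taxa: dict[str, str] = {sid: config.reference_taxon for sid in ref_members}

    truth: dict = {
        "length": L,
        "reference": ref_label,
        "groups": {},
        "seed": seed,
    }

    ref_poly_carrier = 0  # round-robin over non-designated reference samples

    def next_ref_carrier() -> str:
        nonlocal ref_poly_carrier
        ref_poly_carrier = ref_poly_carrier % (config.reference_n - 1) + 1
        return ref_members[ref_poly_carrier]

    for g in config.groups:
        diag_sites = take(g.diagnostic_count)
        extra_sites = take(
            g.closest_pair_total_differences - g.diagnostic_count
        )
        poly_sites = take(g.polymorphic_sites)
        hap = list(ref_seq)
        diag_states = []
        for s in diag_sites:
            hap[s] = _alt_base(rng, ref_seq[s])
            diag_states.append((s + 1, hap[s], ref_seq[s]))
        for s in extra_sites:
            hap[s] = _alt_base(rng, ref_seq[s])
            # one reference sample takes a third state: the site differs in
            # every inter-group pair but is not fixed in the reference
            carrier = next_ref_carrier()
            rows[carrier][s] = _alt_base(rng, ref_seq[s], hap[s])
        members = [f"{g.label}-{i + 1:02d}" for i in range(g.n_samples)]
        for i, sid in enumerate(members):
            rows[sid] = list(hap)
            haplo[sid] = g.label
            taxa[sid] = g.taxon
        for k, s in enumerate(poly_sites):
            # member 0 is the designated closest sample: never a carrier
            if g.n_samples > 1:
                carrier = members[1 + k % (g.n_samples - 1)]
                rows[carrier][s] = _alt_base(rng, hap[s])
        truth["groups"][g.label] = {
            "taxon": g.taxon,
            "n_samples": g.n_samples,
            "diagnostic_count": g.diagnostic_count,
            "diagnostic_sites": diag_states,
            "closest_pair_total_differences": g.closest_pair_total_differences,
            "closest_pair_p": g.closest_pair_total_differences / L,
            "haplotype": "".join(hap),
        }

    # reference's own polymorphism, beyond the extra-site third states
    for s in take(config.reference_polymorphic_sites):
        rows[next_ref_carrier()][s] = _alt_base(rng, ref_seq[s])

    # introgression: recipient-taxon samples that are exact donor haplotypes
    intro_ids: list[str] = []
    if config.introgression is not None:
        spec = config.introgression
        donor_members = [s for s, h in haplo.items() if h == spec.donor]
        recipient_sizes = [
            g.n_samples for g in config.groups if g.taxon == spec.recipient_taxon
        ]
        start = max(recipient_sizes, default=0)
        for i in range(spec.count):
            sid = f"{spec.recipient_taxon[:3].upper()}-{start + i + 1:02d}"
            # copy from the tail of the donor group so carriers of donor
            # polymorphism are reused before the designated closest sample
            source = donor_members[-(i % len(donor_members)) - 1]
            rows[sid] = list(rows[source])
            haplo[sid] = spec.donor
            taxa[sid] = spec.recipient_taxon
            intro_ids.append(sid)
        truth["introgression"] = {
            "donor": spec.donor,
            "recipient_taxon": spec.recipient_taxon,
            "count": spec.count,
            "sample_ids": intro_ids,
        }

    for og in config.outgroups:
        sites = take(og.divergence_sites)
        hap = list(ref_seq)
        for s in sites:
            hap[s] = _alt_base(rng, ref_seq[s])
        for i in range(og.n_samples):
            sid = f"{og.label}-{i + 1:02d}"
            rows[sid] = list(hap)
            haplo[sid] = og.label
            taxa[sid] = og.taxon

    truth["ingroup_labels"] = [ref_label] + [g.label for g in config.groups]
    truth["ingroup_cluster_count"] = 1 + len(config.groups)
    truth["total_cluster_count"] = 1 + len(config.groups) + len(config.outgroups)

    alignment = Alignment({sid: "".join(seq) for sid, seq in rows.items()})
    return FixtureData(
        alignment=alignment,
        haplogroups=GroupingMap(haplo),
        taxa=GroupingMap(taxa),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Jukes–Cantor two-lineage simulator

@dataclass(frozen=True)
class JCSimConfig:
    """Two lineages diverging for ``split_time`` Myr at per-lineage rate
    ``mu`` (substitutions/site/Myr); expected uncorrected distance between
    the sides is (3/4)(1 − exp(−(8/3)·mu·t)). ``introgression_time`` (if
    set, with ``introgression_count`` > 0) transfers donor-side haplotypes
    into that many recipient-side samples at that time before present."""

    length: int = 658
    mu: float = 0.009
    split_time: float = 1.3
    samples_per_side: int = 1
    seed: int = 0
    introgression_time: float | None = None
    introgression_count: int = 0

    def validate(self) -> None:
        if self.length <= 0:
            raise ConfigError("length must be positive")
        if self.mu <= 0:
            raise ConfigError("mu must be positive")
        if self.split_time < 0:
            raise ConfigError("split_time must be non-negative")
        if self.samples_per_side < 1:
            raise ConfigError("samples_per_side must be ≥ 1")
        if self.introgression_time is not None:
            if not 0 <= self.introgression_time <= self.split_time:
                raise ConfigError(
                    "introgression_time must lie in [0, split_time]"
                )
            if self.introgression_count > self.samples_per_side:
                raise ConfigError(
                    "introgression_count exceeds samples_per_side"
                )


def expected_p(mu: float, t: float) -> float:
    """Closed-form JC expectation of the uncorrected pairwise distance."""
    return 0.75 * (1.0 - math.exp(-(8.0 / 3.0) * mu * t))


def _evolve(
    seq: np.ndarray, rate_time: float, rng: np.random.Generator
) -> np.ndarray:
    """One JC branch: per-site Poisson(rate·time) events, each substituting
    a uniformly chosen different base."""
    out = seq.copy()
    hits = rng.poisson(rate_time, size=seq.size)
    for site in np.nonzero(hits)[0]:
        state = out[site]
        for _ in range(hits[site]):
            state = (state + 1 + rng.integers(3)) % 4
        out[site] = state
    return out


def simulate_jc(config: JCSimConfig) -> tuple[Alignment, GroupingMap, dict]:
    """Simulate the two-lineage split; returns alignment, side labels, truth.

    Samples within a side are copies of that side's evolved ancestor;
    introgressed recipient samples instead share the donor lineage's
    history until ``introgression_time`` ago and then evolve on their own
    branch of that length.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.length
    root = rng.integers(4, size=L).astype(np.int64)
    t = config.split_time
    t_i = config.introgression_time

    if t_i is None:
        donor_anc = _evolve(root, config.mu * t, rng)
        recip_anc = _evolve(root, config.mu * t, rng)
        intro_haps: list[np.ndarray] = []
    else:
        donor_mid = _evolve(root, config.mu * (t - t_i), rng)
        donor_anc = _evolve(donor_mid, config.mu * t_i, rng)
        recip_anc = _evolve(root, config.mu * t, rng)
        intro_haps = [
            _evolve(donor_mid, config.mu * t_i, rng)
            for _ in range(config.introgression_count)
        ]

    def decode(codes: np.ndarray) -> str:
        return "".join(_BASES[c] for c in codes)

    records: dict[str, str] = {}
    assignments: dict[str, str] = {}
    for i in range(config.samples_per_side):
        sid = f"donor-{i + 1:02d}"
        records[sid] = decode(donor_anc)
        assignments[sid] = "donor"
    intro_ids: list[str] = []
    for i in range(config.samples_per_side):
        sid = f"recipient-{i + 1:02d}"
        if i < len(intro_haps):
            records[sid] = decode(intro_haps[i])
            intro_ids.append(sid)
        else:
            records[sid] = decode(recip_anc)
        assignments[sid] = "recipient"

    truth = {
        "mu": config.mu,
        "split_time": config.split_time,
        "expected_p": expected_p(config.mu, config.split_time),
        "pairwise_rate_percent_per_myr": 200.0 * config.mu,
        "introgressed_samples": intro_ids,
        "seed": config.seed,
    }
    return Alignment(records), GroupingMap(assignments), truth


def replicate_mean_p(
    config: JCSimConfig, replicates: int, seed: int
) -> float:
    """Mean uncorrected donor/recipient distance over independent
    replicate simulations (one pair each), seeds drawn from *seed*."""
    from .divergence import p_distance

    rng = np.random.default_rng(seed)
    total = 0.0
    for _ in range(replicates):
        rep = replace(
            config,
            samples_per_side=1,
            seed=int(rng.integers(2**31 - 1)),
        )
        aln, _, _ = simulate_jc(rep)
        total += p_distance(aln["donor-01"], aln["recipient-01"]).value
    return total / replicates
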