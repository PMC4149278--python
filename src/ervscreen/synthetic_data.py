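"""Synthetic reference panels and case-control cohorts with known ground truth.

This module emulates the raw material of a provirus presence/absence screen:
a host "mini-genome", a family of proviral elements with a gradient of
nucleotide identity to a designated youngest (reference) element, a set of
insertion loci polymorphic for provirus / solo-LTR / pre-integration /
tandem alleles, and diploid individuals drawn under Hardy-Weinberg
equilibrium with optional per-group frequency enrichment.

Every downstream stage (probe design, virtual digestion, band collation,
in silico PCR, association testing) is exercised against cohorts produced
here, so the generator records enough truth (genotypes, carrier status) to
serve as an oracle.

Coordinates are 0-based, half-open throughout. A target-site duplication of
length ``t`` adds one extra copy of the ``t`` host bases at the insertion
point, so realized lengths are ``flank + insert_length + t``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._seq import random_dna, revcomp, mutate_positions
from .errors import ConfigurationError, DataError

ALLELES = ("pro", "solo", "pre", "tandem")
#: allele states that make an individual a carrier of the provirus
CARRIER_ALLELES = frozenset({"pro", "tandem"})


@dataclass(frozen=True)
class ProviralElement:
    """One proviral sequence: 5'LTR + internal region + 3'LTR."""

    element_id: str
    seq: str
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    identity: float  # percent nucleotide identity to the reference element

    def __post_init__(self):
        if not (0.0 <= self.identity <= 100.0):
            raise ConfigurationError(
                f"{self.element_id}: identity {self.identity} outside [0, 100]"
            )
        s5, e5 = self.ltr5
        s3, e3 = self.ltr3
        if not (0 <= s5 < e5 <= s3 < e3 <= len(self.seq)):
            raise DataError(
                f"{self.element_id}: LTR intervals must be within the element "
                "and non-overlapping"
            )

    @property
    def ltr5_seq(self) -> str:
        return self.seq[self.ltr5[0] : self.ltr5[1]]


@dataclass(frozen=True)
class ProviralLocus:
    """A genomic insertion site and the allele repertoire segregating there."""

    locus_id: str
    contig: str
    insertion_point: int  # 0-based position in the host contig
    strand: str  # '+' or '-'
    element_id: str
    repertoire: frozenset[str]
    tsd_length: int = 0

    def __post_init__(self):
        if self.strand not in "+-":
            raise DataError(f"{self.locus_id}: strand must be '+' or '-'")
        if not self.repertoire:
            raise DataError(f"{self.locus_id}: empty allele repertoire")
        bad = set(self.repertoire) - set(ALLELES)
        if bad:
            raise DataError(f"{self.locus_id}: unknown alleles {sorted(bad)}")
        if self.tsd_length < 0:
            raise DataError(f"{self.locus_id}: negative TSD length")


@dataclass
class ReferencePanel:
    """Host mini-genome + proviral element family + polymorphic loci."""

    host_genome: dict[str, str]
    elements: list[ProviralElement]
    loci: list[ProviralLocus]
    reference_id: str

    def element(self, element_id: str) -> ProviralElement:
        for e in self.elements:
            if e.element_id == element_id:
                return e
        raise KeyError(element_id)

    def locus(self, locus_id: str) -> ProviralLocus:
        for l in self.loci:
            if l.locus_id == locus_id:
                return l
        raise KeyError(locus_id)

    def validate(self) -> None:
        ids = {e.element_id for e in self.elements}
        if self.reference_id not in ids:
            raise DataError(f"reference element {self.reference_id!r} missing")
        for loc in self.loci:
            if loc.contig not in self.host_genome:
                raise DataError(f"{loc.locus_id}: unknown contig {loc.contig!r}")
            if not 0 <= loc.insertion_point < len(self.host_genome[loc.contig]):
                raise DataError(
                    f"{loc.locus_id}: insertion_point {loc.insertion_point} "
                    f"outside contig {loc.contig!r}"
                )
            if loc.element_id not in ids:
                raise DataError(f"{loc.locus_id}: unknown element {loc.element_id!r}")


@dataclass
class PanelConfig:
    """Parameters of the synthetic reference panel.

    Defaults emulate the study conditions: ~60 proviral elements spanning a
    gradient of identity down from the youngest element, with a dozen
    polymorphic insertion loci. Element geometry is scaled to desk size
    (LTR 400 bp, internal 3,200 bp) while preserving the probe-bearing
    leader region just 3' of the 5'LTR.
    """

    n_elements: int = 60
    identities: Sequence[float] | None = None  # explicit per-element identities
    identity_range: tuple[float, float] = (100.0, 88.0)
    ltr_length: int = 400
    internal_length: int = 3200
    n_loci: int = 12
    locus_spacing: int = 14000
    flank: int = 6000
    tsd_length: int = 0
    repertoire: Sequence[str] = ("pro", "solo", "pre")
    n_tandem_loci: int = 0  # first k loci additionally segregate a tandem allele
    # the top guard_protect_k elements (by identity) keep their 5'LTR and
    # leader intact, while all older elements receive forced substitutions
    # inside the guard window: this reproduces the real contrast between a
    # leader region conserved among recent integrations and divergent in the
    # older proviral background, which the probe-design stage exploits
    guard_window: tuple[int, int] | None = None  # element coords; default set below
    guard_protect_k: int = 25
    guard_forced_mismatches: int = 3
    # motifs (plus reverse complements) scrubbed from the reference 5'LTR and
    # leader so the screening enzyme never cuts 5' of the probe; defaults to
    # the BsrI recognition sequence
    forbidden_motifs: Sequence[str] = ("ACTGG",)
    n_recent_locus_elements: int = 10
    seed: int = 0

    def resolved_identities(self) -> list[float]:
        if self.identities is not None:
            vals = [float(v) for v in self.identities]
            if len(vals) != self.n_elements:
                raise ConfigurationError(
                    "identities length must equal n_elements"
                )
        else:
            hi, lo = self.identity_range
            vals = [100.0] + list(
                np.linspace(hi, lo, self.n_elements - 1)
            ) if self.n_elements > 1 else [100.0]
            # element 0 is the reference itself at 100%
            vals = vals[: self.n_elements]
        for v in vals:
            if not (0.0 <= v <= 100.0):
                raise ConfigurationError(f"identity {v} outside [0, 100]")
        return vals


def _element_id(i: int) -> str:
    return f"HML_{i:03d}"


def _scrub_motifs(seq: str, motifs, rng: np.random.Generator) -> str:
    """Destroy every occurrence of the motifs (and reverse complements) by
    substituting a middle base, iterating until none remain."""
    patterns = set()
    for m in motifs:
        m = m.upper()
        patterns.add(m)
        patterns.add(revcomp(m))
    dirty = True
    while dirty:
        dirty = False
        for pat in sorted(patterns):
            i = seq.find(pat)
            while i != -1:
                seq = mutate_positions(seq, [i + len(pat) // 2], rng)
                dirty = True
                i = seq.find(pat, i + 1)
    return seq


def make_reference_panel(config: PanelConfig) -> ReferencePanel:
    """Generate a deterministic reference panel from ``config``.

    The reference element (index 0) is a random sequence with identical
    5' and 3' LTRs; every other element is derived from it by substituting
    exactly ``round((1 - identity/100) * length)`` positions, so measured
    Hamming identity reproduces the requested gradient to within rounding
    (< 1 percentage point for the default element length).
    """
    if config.n_elements < 2:
        raise ConfigurationError("n_elements must be >= 2")
    identities = config.resolved_identities()
    rng = np.random.default_rng(config.seed)

    L_ltr, L_int = config.ltr_length, config.internal_length
    elem_len = 2 * L_ltr + L_int
    ltr = random_dna(rng, L_ltr)
    internal = random_dna(rng, L_int)
    ltr5 = (0, L_ltr)
    ltr3 = (L_ltr + L_int, elem_len)

    guard = config.guard_window
    if guard is None:
        # a probe-sized leader window just 3' of the 5'LTR: the forced
        # mismatches of older elements then always fall inside any window
        # the probe-design stage scores against it
        guard = (L_ltr + 40, L_ltr + 72)
    g0, g1 = guard
    if not L_ltr <= g0 < g1 <= L_ltr + L_int:
        raise ConfigurationError("guard window must lie within the leader")

    # scrub forbidden motifs from the 5'LTR + leader (through the guard
    # window) so the screening enzyme never cuts 5' of the probe site; the
    # scrubbed LTR is reused verbatim as the 3'LTR
    margin = max((len(m) for m in config.forbidden_motifs), default=0)
    prefix_len = g1 + margin
    prefix = _scrub_motifs(
        (ltr + internal)[:prefix_len], config.forbidden_motifs, rng
    )
    ltr = prefix[:L_ltr]
    internal = prefix[L_ltr:] + internal[prefix_len - L_ltr :]
    ref_seq = ltr + internal + ltr

    guard_pos = np.arange(g0, g1)
    # protected elements never mutate in [0, g1): LTR + leader stay intact,
    # so junction arithmetic and probe conservation hold for the recent set
    free_protected = np.arange(g1, elem_len)
    free_older = np.setdiff1d(np.arange(elem_len), guard_pos)

    order = np.argsort([-v for v in identities], kind="stable")
    rank = np.empty(len(identities), dtype=int)
    rank[order] = np.arange(len(identities))

    elements = [ProviralElement(_element_id(0), ref_seq, ltr5, ltr3, 100.0)]
    for i, ident in enumerate(identities[1:], start=1):
        n_mut = int(round((1.0 - ident / 100.0) * elem_len))
        if n_mut == 0:
            seq = ref_seq
        elif rank[i] < config.guard_protect_k:
            pos = rng.choice(
                free_protected, size=min(n_mut, free_protected.size), replace=False
            )
            seq = mutate_positions(ref_seq, pos, rng)
        else:
            k = min(config.guard_forced_mismatches, n_mut, guard_pos.size)
            pos_in = rng.choice(guard_pos, size=k, replace=False)
            pos_out = rng.choice(
                free_older, size=min(n_mut - k, free_older.size), replace=False
            )
            seq = mutate_positions(ref_seq, np.concatenate([pos_in, pos_out]), rng)
        elements.append(ProviralElement(_element_id(i), seq, ltr5, ltr3, float(ident)))

    # host mini-genome: one contig, loci evenly spaced with jitter
    n_loci = config.n_loci
    contig_len = 2 * config.flank + n_loci * config.locus_spacing
    host = {"chrS": random_dna(rng, contig_len)}
    n_recent = min(config.n_recent_locus_elements, config.n_elements)
    loci = []
    for j in range(n_loci):
        base = config.flank + j * config.locus_spacing + config.locus_spacing // 2
        ip = int(base + rng.integers(-config.locus_spacing // 8,
                                     config.locus_spacing // 8 + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        rep = set(config.repertoire)
        if j < config.n_tandem_loci:
            rep.add("tandem")
        loci.append(
            ProviralLocus(
                locus_id=f"L{j:02d}",
                contig="chrS",
                insertion_point=ip,
                strand=strand,
                element_id=_element_id(j % n_recent),
                repertoire=frozenset(rep),
                tsd_length=config.tsd_length,
            )
        )
    panel = ReferencePanel(host, elements, loci, reference_id=_element_id(0))
    panel.validate()
    return panel


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortSpec:
    """Case-control cohort parameters.

    ``frequencies`` maps each locus to the per-haplotype probability of the
    proviral allele, either a single float (both groups) or a
    ``(f_case, f_control)`` pair (explicit enrichment). The remaining
    probability mass is split between solo-LTR and pre-integration alleles:
    a ``solo_fraction`` share goes to "solo" when the repertoire allows it,
    the rest to "pre". When a locus also segregates a tandem allele,
    ``tandem_fraction`` of the proviral mass is realized as "tandem".
    """

    n_cases: int
    n_controls: int
    frequencies: Mapping[str, float | tuple[float, float]]
    solo_fraction: float = 0.5
    tandem_fraction: float = 0.0
    snp_rate: float = 0.0
    seed: int = 0

    def group_frequency(self, locus_id: str, group: str) -> float:
        f = self.frequencies[locus_id]
        if isinstance(f, (tuple, list)):
            f = f[0] if group == "case" else f[1]
        f = float(f)
        if not 0.0 <= f <= 1.0:
            raise ConfigurationError(f"{locus_id}: frequency {f} outside [0, 1]")
        return f


@dataclass(frozen=True)
class Individual:
    individual_id: str
    group: str  # 'case' | 'control'
    genotypes: Mapping[str, tuple[str, str]]  # locus_id -> ordered allele pair

    def is_carrier(self, locus_id: str) -> bool:
        return any(a in CARRIER_ALLELES for a in self.genotypes[locus_id])


def _allele_distribution(locus: ProviralLocus, f: float, spec: CohortSpec):
    states, probs = [], []
    pro_mass = f
    if "tandem" in locus.repertoire and spec.tandem_fraction > 0:
        states.append("tandem")
        probs.append(pro_mass * spec.tandem_fraction)
        pro_mass *= 1.0 - spec.tandem_fraction
    states.append("pro")
    probs.append(pro_mass)
    rest = 1.0 - f
    if "solo" in locus.repertoire:
        states.append("solo")
        probs.append(rest * spec.solo_fraction)
        rest *= 1.0 - spec.solo_fraction
    states.append("pre")
    probs.append(rest)
    return states, np.asarray(probs)


def simulate_cohort(panel: ReferencePanel, spec: CohortSpec) -> list[Individual]:
    """Draw diploid individuals under Hardy-Weinberg at every locus.

    Haplotypes are independent across loci and individuals; the expected
    carrier fraction at proviral-allele frequency ``f`` is ``1 - (1 - f)**2``.
    Deterministic for a fixed ``spec.seed``.
    """
    if spec.n_cases <= 0 or spec.n_controls <= 0:
        raise ConfigurationError("group sizes must be positive")
    panel_ids = {l.locus_id for l in panel.loci}
    missing = panel_ids - set(spec.frequencies)
    if missing:
        raise ConfigurationError(f"no frequency given for loci: {sorted(missing)}")
    extra = set(spec.frequencies) - panel_ids
    if extra:
        raise ConfigurationError(f"frequencies for unknown loci: {sorted(extra)}")

    rng = np.random.default_rng(spec.seed)
    individuals: list[Individual] = []
    roster = [("case", i) for i in range(spec.n_cases)] + [
        ("control", i) for i in range(spec.n_controls)
    ]
    for group, i in roster:
        geno = {}
        for locus in panel.loci:
            f = spec.group_frequency(locus.locus_id, group)
            states, probs = _allele_distribution(locus, f, spec)
            pair = tuple(
                states[k] for k in rng.choice(len(states), size=2, p=probs)
            )
            geno[locus.locus_id] = pair
        individuals.append(
            Individual(f"{group}_{i:03d}", group, geno)
        )
    return individuals


def carrier_matrix(cohort: Sequence[Individual], panel: ReferencePanel):
    """Ground-truth carrier status, individuals x loci (dict of dicts)."""
    return {
        ind.individual_id: {
            loc.locus_id: ind.is_carrier(loc.locus_id) for loc in panel.loci
        }
        for ind in cohort
    }


# ---------------------------------------------------------------------------
# genome realization


def allele_insert(element: ProviralElement, allele: str) -> str:
    """The sequence inserted at the locus for a given allele, element-oriented.

    pre    -> '' (host unchanged)
    pro    -> the full element
    solo   -> the element's 5'LTR alone
    tandem -> two element bodies sharing one central LTR
    """
    if allele == "pre":
        return ""
    if allele == "pro":
        return element.seq
    if allele == "solo":
        return element.ltr5_seq
    if allele == "tandem":
        # element + (internal + 3'LTR): the first body's 3'LTR doubles as the
        # second body's 5'LTR
        return element.seq + element.seq[element.ltr5[1] :]
    raise DataError(f"unknown allele {allele!r}")


def realize_haplotype(
    panel: ReferencePanel,
    locus: ProviralLocus,
    allele: str,
    flank: int = 6000,
    snp_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> str:
    """Assemble the regional haplotype sequence around one locus.

    Region = ``flank`` bp of host on each side of the insertion point. For a
    non-empty allele the insert (reverse-complemented on '-' strand loci) is
    placed at the insertion point together with one extra copy of the
    ``tsd_length`` host bases immediately 3' of it. SNPs, if requested, are
    applied to the assembled sequence at ``snp_rate`` per bp.
    """
    if allele not in locus.repertoire:
        raise DataError(
            f"{locus.locus_id}: allele {allele!r} not in repertoire "
            f"{sorted(locus.repertoire)}"
        )
    host = panel.host_genome[locus.contig]
    ip, t = locus.insertion_point, locus.tsd_length
    a = max(0, ip - flank)
    b = min(len(host), ip + flank)
    insert = allele_insert(panel.element(locus.element_id), allele)
    if locus.strand == "-":
        insert = revcomp(insert)
    if allele == "pre":
        seq = host[a:b]
    else:
        seq = host[a : ip + t] + insert + host[ip:b]
    if snp_rate > 0:
        if rng is None:
            raise ConfigurationError("snp_rate > 0 requires an rng")
        n = rng.binomial(len(seq), snp_rate)
        if n:
            pos = rng.choice(len(seq), size=n, replace=False)
            seq = mutate_positions(seq, pos, rng)
    return seq


def realize_genome(
    individual: Individual,
    panel: ReferencePanel,
    flank: int = 6000,
    snp_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, tuple[str, str]]:
    """Both regional haplotypes at every locus for one individual.

    SNP randomness is derived from ``(seed, individual id, locus, haplotype)``
    so realization is reproducible regardless of call order.
    """
    out = {}
    for locus in panel.loci:
        pair = individual.genotypes[locus.locus_id]
        haps = []
        for h, allele in enumerate(pair):
            rng = None
            if snp_rate > 0:
                key = zlib.crc32(
                    f"{individual.individual_id}:{locus.locus_id}:{h}".encode()
                )
                rng = np.random.default_rng([seed, key])
            haps.append(
                realize_haplotype(panel, locus, allele, flank, snp_rate, rng)
            )
        out[locus.locus_id] = (haps[0], haps[1])
    return out


def element_rows(panel: ReferencePanel) -> dict[str, str]:
    """Element sequences keyed by id, as equal-length alignment rows.

    Synthetic elements are substitution-only derivatives of the reference, so
    the raw sequences already form a gap-free alignment.
    """
    return {e.element_id: e.seq for e in panel.elements}
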