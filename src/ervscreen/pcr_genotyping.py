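"""In silico PCR and three-primer allele genotyping.

Each polymorphic locus is typed with two primer pairs built from three
primers: set I (host forward primer upstream of the insertion + reverse
primer in the proviral leader just 3' of the 5'LTR) amplifies only when a
provirus is present; set II (the same host forward primer + a reverse
primer in the host flank downstream of the integration site) spans the
insertion point and yields a short product on the pre-integration allele
or a product longer by one LTR on the solo-LTR allele. Together the two
sets resolve pro / solo / pre diploid genotypes; set I alone defines
carrier status.

Product sizes follow the UCSC in silico PCR convention: 5' end of the
forward primer to the 5' end of the reverse primer, inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import mismatch_profile, revcomp
from .errors import ConfigurationError, DataError
from .synthetic_data import (
    Individual,
    ProviralLocus,
    ReferencePanel,
    realize_haplotype,
)

MIN_PRIMER = 15


@dataclass(frozen=True)
class PrimerSet:
    """Three-primer design for one locus (stored as two pairs)."""

    locus_id: str
    forward_I: str
    reverse_I: str
    forward_II: str
    reverse_II: str
    size_I: int  # expected provirus 5'LTR-junction product
    size_II_solo: int
    size_II_pre: int

    def __post_init__(self):
        for name in ("forward_I", "reverse_I", "forward_II", "reverse_II"):
            if len(getattr(self, name)) < MIN_PRIMER:
                raise ConfigurationError(
                    f"{self.locus_id}: {name} shorter than {MIN_PRIMER} nt"
                )
        if min(self.size_I, self.size_II_solo, self.size_II_pre) <= 0:
            raise ConfigurationError(f"{self.locus_id}: product sizes must be > 0")
        if self.size_II_solo <= self.size_II_pre:
            raise ConfigurationError(
                f"{self.locus_id}: solo product must exceed pre product"
            )


@dataclass(frozen=True)
class AlleleCall:
    individual_id: str
    locus_id: str
    call: str  # e.g. 'pro/pre', 'carrier-only', 'no-amplification'
    products_I: tuple[int, ...] = ()
    products_II: tuple[int, ...] = ()

    @property
    def carrier(self) -> bool:
        return len(self.products_I) > 0


def _primer_sites(template: str, primer: str, max_mismatch: int, anchor: int):
    """Start positions where ``primer`` binds the top strand, 3' end anchored."""
    prof = mismatch_profile(template, primer)
    if prof.size == 0:
        return np.zeros(0, dtype=np.int64)
    ok = prof <= max_mismatch
    if max_mismatch > 0 and anchor > 0:
        tail = mismatch_profile(template, primer[-anchor:])
        # tail profile index i corresponds to primer start i - (len - anchor)
        shift = len(primer) - anchor
        ok &= tail[shift : shift + prof.size] == 0
    return np.flatnonzero(ok)


def _one_orientation(template, fwd, rev, max_product, max_mismatch, anchor):
    sizes = []
    f_sites = _primer_sites(template, fwd, max_mismatch, anchor)
    if f_sites.size == 0:
        return sizes
    r_sites = _primer_sites(template, revcomp(rev), max_mismatch, anchor)
    for f in f_sites:
        for r in r_sites:
            size = int(r) + len(rev) - int(f)
            if len(fwd) + len(rev) <= size <= max_product:
                sizes.append(size)
    return sizes


def insilico_pcr(
    template: str,
    fwd: str,
    rev: str,
    max_product: int = 5000,
    max_mismatch: int = 0,
    anchor: int = 3,
) -> list[int]:
    """All product sizes for a primer pair on a template, both orientations.

    A product forms for every forward-primer site with a downstream
    reverse-complemented reverse-primer site within ``max_product`` bp.
    Binding is exact by default; with ``max_mismatch > 0``, internal
    mismatches are tolerated but the 3'-terminal ``anchor`` bases must
    match perfectly (extension requires an annealed 3' end).
    """
    if len(fwd) < MIN_PRIMER or len(rev) < MIN_PRIMER:
        raise ConfigurationError(f"primers must be >= {MIN_PRIMER} nt")
    template = template.upper()
    sizes = _one_orientation(template, fwd, rev, max_product, max_mismatch, anchor)
    sizes += _one_orientation(
        revcomp(template), fwd, rev, max_product, max_mismatch, anchor
    )
    return sorted(sizes)


def _classify_II(products: Sequence[int], primers: PrimerSet, tol: int):
    """Map each set-II product to 'solo' or 'pre' by nearer expected size."""
    states = []
    for size in products:
        d_solo = abs(size - primers.size_II_solo)
        d_pre = abs(size - primers.size_II_pre)
        if min(d_solo, d_pre) > tol or d_solo == d_pre:
            continue  # off-size or undecidable: no call from this product
        states.append("solo" if d_solo < d_pre else "pre")
    return states


def genotype_locus(
    haplotypes: Sequence[str],
    primers: PrimerSet,
    size_tolerance: int = 50,
    max_product: int = 5000,
    max_mismatch: int = 0,
    individual_id: str = "",
) -> AlleleCall:
    """Call the diploid allele state at one locus from realized haplotypes.

    With two haplotypes the call is composed per haplotype (set-I product at
    the expected size => proviral allele; otherwise solo vs pre by the
    nearer set-II size). With a single merged template, phase is
    unavailable: a unique pair of allele states is still called, a lone
    proviral signal falls back to 'carrier-only', and silence on both sets
    is 'no-amplification'.
    """
    if not 1 <= len(haplotypes) <= 2:
        raise DataError("expected one merged template or two haplotypes")

    def evidence(template):
        pI = insilico_pcr(template, primers.forward_I, primers.reverse_I,
                          max_product, max_mismatch)
        pII = insilico_pcr(template, primers.forward_II, primers.reverse_II,
                           max_product, max_mismatch)
        pro = any(abs(s - primers.size_I) <= size_tolerance for s in pI)
        states = _classify_II(pII, primers, size_tolerance)
        return pI, pII, pro, states

    if len(haplotypes) == 2:
        calls, all_I, all_II = [], [], []
        for h in haplotypes:
            pI, pII, pro, states = evidence(h)
            all_I += pI
            all_II += pII
            if pro:
                calls.append("pro")
            elif states:
                calls.append(states[0])
            else:
                calls.append(None)
        if any(c is None for c in calls):
            known = [c for c in calls if c is not None]
            call = "carrier-only" if "pro" in known else "no-amplification"
        else:
            call = "/".join(sorted(calls, key=("pro", "solo", "pre").index))
        return AlleleCall(individual_id, primers.locus_id, call,
                          tuple(sorted(all_I)), tuple(sorted(all_II)))

    pI, pII, pro, states = evidence(haplotypes[0])
    present = (["pro"] if pro else []) + sorted(set(states),
                                                key=("solo", "pre").index)
    if len(present) == 2:
        call = "/".join(sorted(present, key=("pro", "solo", "pre").index))
    elif len(present) == 1:
        call = "carrier-only" if present == ["pro"] else f"{present[0]}/{present[0]}"
    else:
        call = "no-amplification"
    return AlleleCall(individual_id, primers.locus_id, call,
                      tuple(sorted(pI)), tuple(sorted(pII)))


def carrier_table(
    calls: Sequence[AlleleCall], groups: Mapping[str, str]
) -> pd.DataFrame:
    """Per-locus 2x2 carrier counts (feeds the association module)."""
    if not calls:
        raise DataError("no allele calls supplied")
    n_cases = sum(1 for g in groups.values() if g == "case")
    n_controls = len(groups) - n_cases
    rows = {}
    for c in calls:
        row = rows.setdefault(
            c.locus_id,
            {"locus_id": c.locus_id, "case_pos": 0, "case_n": n_cases,
             "control_pos": 0, "control_n": n_controls},
        )
        if c.carrier:
            row["case_pos" if groups[c.individual_id] == "case" else
                "control_pos"] += 1
    df = pd.DataFrame(list(rows.values()))
    df["case_freq"] = df["case_pos"] / df["case_n"]
    df["control_freq"] = df["control_pos"] / df["control_n"]
    return df


# ---------------------------------------------------------------------------
# primer design for synthetic loci


def design_primer_set(
    panel: ReferencePanel,
    locus: ProviralLocus,
    primer_len: int = 20,
    up_gap: int = 150,
    down_gap: int = 150,
    leader_offset: int = 60,
    flank: int = 6000,
    max_product: int = 5000,
) -> PrimerSet:
    """Extract a locus-specific three-primer set from the panel sequences.

    Primers are taken directly from the reference coordinates (host flank
    within ~``up_gap`` bp of the provirus edge; proviral leader just 3' of
    the 5'LTR; host flank ``down_gap`` bp downstream of the integration
    site) and the expected product sizes are measured by running the in
    silico PCR on clean single-allele templates — the synthetic analogue of
    validating a primer table against the reference genome. This is a
    coordinate lookup, not a thermodynamic primer design.
    """
    element = panel.element(locus.element_id)
    l5e = element.ltr5[1]
    host_len = len(panel.host_genome[locus.contig])
    ip, t = locus.insertion_point, locus.tsd_length

    def frame_of(allele):
        hap = realize_haplotype(panel, locus, allele, flank=flank)
        return hap if locus.strand == "+" else revcomp(hap)

    # element-oriented frame: host upstream | [insert] | host downstream;
    # the element's left edge in that frame depends on strand and TSD
    if locus.strand == "+":
        jf = (ip + t) - max(0, ip - flank)
    else:
        jf = min(host_len, ip + flank) - ip
    pro_frame = frame_of("pro")
    fwd = pro_frame[jf - up_gap - primer_len : jf - up_gap]
    rev_I = revcomp(
        pro_frame[jf + l5e + leader_offset : jf + l5e + leader_offset + primer_len]
    )
    down_start = jf + len(element.seq) + down_gap
    rev_II = revcomp(pro_frame[down_start : down_start + primer_len])

    def product(allele, f, r):
        sizes = insilico_pcr(frame_of(allele), f, r, max_product=max_product)
        if len(sizes) != 1:
            raise DataError(
                f"{locus.locus_id}: expected one {allele} product, got {sizes}"
            )
        return sizes[0]

    size_I = product("pro", fwd, rev_I)
    size_II_pre = product("pre", fwd, rev_II)
    if "solo" in locus.repertoire:
        size_II_solo = product("solo", fwd, rev_II)
    else:
        size_II_solo = size_II_pre + (element.ltr5[1] - element.ltr5[0])
    return PrimerSet(
        locus_id=locus.locus_id,
        forward_I=fwd,
        reverse_I=rev_I,
        forward_II=fwd,
        reverse_II=rev_II,
        size_I=size_I,
        size_II_solo=size_II_solo,
        size_II_pre=size_II_pre,
    )


def genotype_cohort(
    cohort: Sequence[Individual],
    panel: ReferencePanel,
    primer_sets: Mapping[str, PrimerSet],
    regions: Mapping[str, Mapping[str, Sequence[str]]],
    size_tolerance: int = 50,
    max_product: int = 5000,
) -> list[AlleleCall]:
    """Genotype every individual at every locus from realized regions.

    ``regions`` maps individual -> locus -> haplotype sequences (as produced
    by :func:`ervscreen.synthetic_data.realize_genome`).
    """
    calls = []
    for ind in cohort:
        for locus in panel.loci:
            calls.append(
                genotype_locus(
                    regions[ind.individual_id][locus.locus_id],
                    primer_sets[locus.locus_id],
                    size_tolerance=size_tolerance,
                    max_product=max_product,
                    individual_id=ind.individual_id,
                )
            )
    return calls
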