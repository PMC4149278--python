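"""Restriction-enzyme selection and junction-fragment prediction.

The screen detects each proviral insertion as a single probe-containing
restriction fragment spanning the 5' host/provirus junction: enzymes are
required to cut at least once within the provirus body but never inside the
5'LTR, so the fragment runs from the nearest cut in the host flank 5' of
the insertion point to the first cut within the element 3' of the probe.
Fragment size therefore reads out how much host DNA separates the insertion
from the nearest upstream restriction site — a per-locus signature.

Fragment boundaries are actual cut positions (recognition start + cut
offset), not recognition-site starts; for non-palindromic downstream
cutters such as BsrI the two strand-resolved cut coordinates differ by a
few bp, which is far below gel resolution and absorbed by the band-matching
tolerance downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import revcomp
from .errors import ConfigurationError, ContractViolation
from .probe_design import probe_hits
from .synthetic_data import ProviralLocus, ReferencePanel, allele_insert

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]",
    "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGT]",
}


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease.

    ``cut_offset`` is the top-strand cut position relative to the start of
    the recognition sequence on the strand where the site reads 5'->3'. It
    may be negative or exceed the recognition length (downstream cutters).
    BsrI (ACTGG 1/-1) cuts the top strand 1 nt past its 5-bp site, hence
    offset 6.
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self):
        if len(self.site) < 4:
            raise ConfigurationError(
                f"{self.name}: recognition sequence must be >= 4 nt"
            )
        bad = set(self.site.upper()) - set(IUPAC)
        if bad:
            raise ConfigurationError(f"{self.name}: non-IUPAC symbols {sorted(bad)}")

    @property
    def pattern(self) -> str:
        return "".join(IUPAC[c] for c in self.site.upper())


BSRI = Enzyme("BsrI", "ACTGG", 6)

#: BsrI plus a handful of common enzymes; user tables extend this via TSV
DEFAULT_ENZYMES = [
    BSRI,
    Enzyme("EcoRI", "GAATTC", 1),
    Enzyme("HindIII", "AAGCTT", 1),
    Enzyme("BamHI", "GGATCC", 1),
    Enzyme("DraI", "TTTAAA", 3),
    Enzyme("PstI", "CTGCAG", 5),
    Enzyme("SspI", "AATATT", 3),
    Enzyme("HinfI", "GANTC", 1),
]


def find_sites(seq: str, enzyme: Enzyme) -> np.ndarray:
    """Top-strand cut coordinates from recognition matches on both strands.

    A forward match at ``p`` cuts at ``p + cut_offset``; a match of the
    reverse-complemented site at ``p`` cuts at ``p + len(site) - cut_offset``
    (the mirrored coordinate). Cuts falling outside the molecule are
    dropped. Returns a sorted, deduplicated int array.
    """
    seq = seq.upper()
    L = len(enzyme.site)
    cuts: list[int] = []
    fwd = re.compile(f"(?=({enzyme.pattern}))")
    for m in fwd.finditer(seq):
        c = m.start() + enzyme.cut_offset
        if 0 <= c <= len(seq):
            cuts.append(c)
    rc_site = revcomp(enzyme.site)
    if rc_site != enzyme.site.upper():
        rev = re.compile(
            "(?=(" + "".join(IUPAC[c] for c in rc_site) + "))"
        )
        for m in rev.finditer(seq):
            c = m.start() + L - enzyme.cut_offset
            if 0 <= c <= len(seq):
                cuts.append(c)
    else:
        # palindromic: the bottom-strand cut of the same site, mirrored
        for m in fwd.finditer(seq):
            c = m.start() + L - enzyme.cut_offset
            if 0 <= c <= len(seq):
                cuts.append(c)
    return np.unique(np.asarray(cuts, dtype=np.int64))


def select_enzymes(
    element_seq: str,
    ltr5: tuple[int, int],
    enzymes: Iterable[Enzyme] = DEFAULT_ENZYMES,
) -> list[Enzyme]:
    """Enzymes cutting >= once in the element but never within the 5'LTR.

    A cut at position ``c`` severs the bond between ``c-1`` and ``c``; it is
    "within" the 5'LTR when ``ltr5.start < c < ltr5.end``.
    """
    s, e = ltr5
    if not 0 <= s < e <= len(element_seq):
        raise ContractViolation("5'LTR interval outside element")
    keep = []
    for enz in enzymes:
        cuts = find_sites(element_seq, enz)
        in_ltr = (cuts > s) & (cuts < e)
        if in_ltr.any():
            continue
        if len(cuts) - int(in_ltr.sum()) >= 1:
            keep.append(enz)
    return keep


@dataclass(frozen=True)
class JunctionFragment:
    """A predicted probe-containing host/provirus junction fragment.

    ``size`` is None when no bounding cut exists within the search horizon
    ("undetectably large"). ``upstream_cut`` is the host-side boundary in
    host-contig coordinates; ``downstream_cut`` the provirus-side boundary
    in element coordinates (3' of the probe). Either may be None when the
    corresponding boundary fell outside host or element (e.g. a
    junction-spanning recognition site).
    """

    locus_id: str
    allele: str
    size: int | None
    upstream_cut: int | None
    downstream_cut: int | None
    contains_probe: bool = True

    @property
    def detectable(self) -> bool:
        return self.size is not None


def predict_junction_fragment(
    locus: ProviralLocus,
    panel: ReferencePanel,
    probe_interval: tuple[int, int],
    enzyme: Enzyme,
    horizon: int = 20000,
    allele: str = "pro",
) -> JunctionFragment:
    """Size of the probe-containing junction fragment for one locus.

    ``probe_interval`` is the probe's position in element coordinates; it
    must lie 3' of the 5'LTR and 5' of the first internal cut. The fragment
    is bracketed by the nearest cut 5' of the probe (in the host flank) and
    the first cut 3' of it (inside the element). Cut sites are searched on
    the locally assembled host+TSD+element composite so recognition sites
    straddling the junction are resolved exactly as in a real digest. When
    no bounding cut exists within ``horizon`` bp of the insertion point the
    fragment is reported as undetectably large (size None), not an error.
    """
    element = panel.element(locus.element_id)
    ps, pe = probe_interval
    if ps < element.ltr5[1]:
        raise ContractViolation(
            f"{locus.locus_id}: probe must lie 3' of the 5'LTR"
        )
    insert = allele_insert(element, allele)
    if allele not in ("pro", "tandem"):
        raise ContractViolation("junction fragments exist only for pro/tandem")
    Le = len(insert)

    elem_cuts = find_sites(insert, enzyme)
    blocking = elem_cuts[(elem_cuts > 0) & (elem_cuts < pe) & (elem_cuts < Le)]
    if blocking.size:
        raise ContractViolation(
            f"{locus.locus_id}: {enzyme.name} cuts the element at "
            f"{blocking.tolist()} 5' of (or within) the probe at {probe_interval}"
        )

    host = panel.host_genome[locus.contig]
    ip, t = locus.insertion_point, locus.tsd_length
    a0 = max(0, ip - horizon)
    b0 = min(len(host), ip + horizon)
    oriented = insert if locus.strand == "+" else revcomp(insert)
    composite = host[a0 : ip + t] + oriented + host[ip:b0]
    j = (ip + t) - a0  # composite coordinate of the element's left edge
    jend = j + Le

    if locus.strand == "+":
        probe_c = (j + ps, j + pe)
    else:
        probe_c = (jend - pe, jend - ps)

    cuts = find_sites(composite, enzyme)
    left = cuts[cuts <= probe_c[0]]
    right = cuts[cuts >= probe_c[1]]
    up = int(left.max()) if left.size else None
    down = int(right.min()) if right.size else None
    if up is None or down is None:
        return JunctionFragment(locus.locus_id, allele, None, None, None)

    if locus.strand == "+":
        host_cut = a0 + up if up < j else None
        elem_cut = down - j if down <= jend else None
    else:
        host_cut = ip + (down - jend) if down > jend else None
        elem_cut = Le - (up - j) if up >= j else None
    return JunctionFragment(
        locus.locus_id, allele, int(down - up), host_cut, elem_cut
    )


def digest_pattern(
    regions: Mapping[str, Sequence[str]] | Sequence[str],
    enzyme: Enzyme,
    probe: str,
    max_mismatch: int = 2,
    size_window: tuple[int, int] = (500, 10000),
    individual_id: str = "",
    group: str = "",
):
    """Full virtual digest of one individual's realized regional sequences.

    Emits a band for every internal fragment that wholly contains a probe
    hit (either strand, <= ``max_mismatch``) and whose size lies within
    ``size_window``. Identical sizes collapse to a single band — diploid
    duplicates and cross-locus coincidences are indistinguishable on a gel.
    Fragments truncated by a region boundary (no real cut on one side) are
    censored, matching the finite search horizon of fragment prediction.
    """
    from .band_analysis import BandPattern

    if isinstance(regions, Mapping):
        seqs = [s for pair in regions.values() for s in pair]
    else:
        seqs = list(regions)
    lo, hi = size_window
    sizes: set[int] = set()
    for seq in seqs:
        cuts = find_sites(seq, enzyme)
        if cuts.size < 2:
            continue
        for hit in probe_hits(probe, seq, max_mismatch):
            h0, h1 = hit.start, hit.start + len(probe)
            idx = int(np.searchsorted(cuts, h0, side="right"))
            if idx == 0 or idx == cuts.size:
                continue  # edge fragment: censored
            if cuts[idx] < h1:
                continue  # a cut severs the probe site
            size = int(cuts[idx] - cuts[idx - 1])
            if lo <= size <= hi:
                sizes.add(size)
    return BandPattern(
        individual_id=individual_id,
        group=group,
        sizes=tuple(sorted(sizes, reverse=True)),
    )
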