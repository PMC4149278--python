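"""Cut-site finding, enzyme selection and junction-fragment prediction.

The central check is oracle equivalence: predicted junction-fragment sizes
must match a full composite digest performed with an independent, loop-based
site scanner written in this file.
"""

import dataclasses

import numpy as np
import pytest

from ervscreen._seq import random_dna, revcomp
from ervscreen.errors import ContractViolation
from ervscreen.synthetic_data import (
    make_reference_panel,
    realize_haplotype,
)
from ervscreen.virtual_digest import (
    BSRI,
    Enzyme,
    digest_pattern,
    find_sites,
    predict_junction_fragment,
    select_enzymes,
)

from conftest import small_panel_config

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
    "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def oracle_cuts(seq: str, enzyme: Enzyme) -> list[int]:
    """Independent site scanner: explicit per-position loops, no regex."""
    seq = seq.upper()
    L = len(enzyme.site)

    def matches(fragment: str, site: str) -> bool:
        return len(fragment) == len(site) and all(
            ch in IUPAC_SETS[s] for ch, s in zip(fragment, site.upper())
        )

    cuts = set()
    rc_site = revcomp(enzyme.site)
    for p in range(len(seq) - L + 1):
        window = seq[p : p + L]
        if matches(window, enzyme.site):
            c = p + enzyme.cut_offset
            if 0 <= c <= len(seq):
                cuts.add(c)
        if matches(window, rc_site):
            c = p + L - enzyme.cut_offset
            if 0 <= c <= len(seq):
                cuts.add(c)
    return sorted(cuts)


def oracle_junction_size(panel, locus, probe_interval, enzyme, flank=6000):
    """Full composite digest: assemble the pro haplotype, cut everywhere,
    return the size of the fragment containing the probe site."""
    hap = realize_haplotype(panel, locus, "pro", flank=flank)
    element = panel.element(locus.element_id)
    probe = element.seq[probe_interval[0] : probe_interval[1]]
    target = probe if locus.strand == "+" else revcomp(probe)
    start = hap.find(target)
    assert start != -1 and hap.find(target, start + 1) == -1
    cuts = oracle_cuts(hap, enzyme)
    left = [c for c in cuts if c <= start]
    right = [c for c in cuts if c >= start + len(probe)]
    if not left or not right:
        return None
    return min(right) - max(left)


class TestFindSites:
    def test_no_recognition_matches_empty(self):
        assert find_sites("AAAAAAAAAA", BSRI).size == 0

    def test_hand_placed_bsri_cuts(self):
        # forward site at 100 cuts at 106; reverse-strand site (CCAGT on the
        # top strand) at 50 cuts at 50 + 5 - 6 = 49
        seq = list("A" * 200)
        seq[100:105] = "ACTGG"
        seq[50:55] = "CCAGT"
        cuts = find_sites("".join(seq), BSRI)
        assert cuts.tolist() == [49, 106]

    def test_palindromic_enzyme_mirrors_on_revcomp(self, rng):
        ecorv_like = Enzyme("EcoRI", "GAATTC", 1)
        seq = random_dna(rng, 3000)
        fwd = find_sites(seq, ecorv_like)
        rev = find_sites(revcomp(seq), ecorv_like)
        assert sorted(len(seq) - c for c in fwd) == rev.tolist()

    def test_agrees_with_loop_oracle_incl_iupac(self, rng):
        seq = random_dna(rng, 4000)
        for enz in (BSRI, Enzyme("HinfI", "GANTC", 1),
                    Enzyme("EcoRI", "GAATTC", 1)):
            assert find_sites(seq, enz).tolist() == oracle_cuts(seq, enz)


class TestSelectEnzymes:
    def make_element(self, rng):
        # scrubbed background, then plant sites by hand
        from ervscreen.synthetic_data import _scrub_motifs

        body = _scrub_motifs(random_dna(rng, 2000),
                             ["ACTGG", "GAATTC", "AAGCTT"], rng)
        return body

    def test_filter_rules(self, rng):
        body = self.make_element(rng)
        ltr5 = (0, 400)
        ltr_cutter = list(body)
        ltr_cutter[200:206] = "GAATTC"  # only cut inside the 5'LTR
        body_cutter = list(body)
        body_cutter[1000:1005] = "ACTGG"  # one cut in gag, none in LTR
        both = list(ltr_cutter)
        both[1000:1005] = "ACTGG"

        enzymes = [BSRI, Enzyme("EcoRI", "GAATTC", 1),
                   Enzyme("HindIII", "AAGCTT", 1)]
        # cut only inside 5'LTR -> excluded; no cut anywhere -> excluded
        assert select_enzymes("".join(ltr_cutter), ltr5, enzymes) == []
        # one cut in the body, none in the LTR -> included
        assert select_enzymes("".join(body_cutter), ltr5, enzymes) == [BSRI]
        # cuts in both body and LTR -> the LTR cut disqualifies
        kept = select_enzymes("".join(both), ltr5, enzymes)
        assert [e.name for e in kept] == ["BsrI"]

    def test_default_panel_reference_passes_bsri(self, small_panel):
        ref = small_panel.element(small_panel.reference_id)
        kept = select_enzymes(ref.seq, ref.ltr5)
        assert "BsrI" in [e.name for e in kept]


class TestPredictJunctionFragment:
    def test_toy_hand_computed_size(self, rng):
        """Host cut 500 bp upstream, first internal cut 1200 bp into the
        element (3' of probe), tsd=0 -> size 1700."""
        from ervscreen.synthetic_data import (
            ProviralElement, ProviralLocus, ReferencePanel, _scrub_motifs,
        )

        host = list(_scrub_motifs(random_dna(rng, 20000), ["ACTGG"], rng))
        ip = 10000
        host[ip - 500 - 6 : ip - 500 - 1] = "ACTGG"  # cut at ip-500
        elem = list(_scrub_motifs(random_dna(rng, 3000), ["ACTGG"], rng))
        elem[1200 - 6 : 1200 - 1] = "ACTGG"  # cut at 1200
        element = ProviralElement("E", "".join(elem), (0, 300), (2700, 3000),
                                  100.0)
        locus = ProviralLocus("toy", "c", ip, "+", "E",
                              frozenset({"pro", "pre"}), 0)
        panel = ReferencePanel({"c": "".join(host)}, [element], [locus], "E")
        frag = predict_junction_fragment(locus, panel, (400, 432), BSRI)
        assert frag.size == 1700
        assert frag.upstream_cut == ip - 500
        assert frag.downstream_cut == 1200
        # documented size identity: (ip - upstream) + downstream at tsd=0
        assert frag.size == (ip - frag.upstream_cut) + frag.downstream_cut

    def test_probe_behind_internal_cut_is_contract_violation(self, rng):
        from ervscreen.synthetic_data import (
            ProviralElement, ProviralLocus, ReferencePanel, _scrub_motifs,
        )

        host = _scrub_motifs(random_dna(rng, 8000), ["ACTGG"], rng)
        elem = list(_scrub_motifs(random_dna(rng, 2000), ["ACTGG"], rng))
        elem[350:355] = "ACTGG"  # cut at 361, 5' of the probe at 400
        elem[1500:1505] = "ACTGG"
        element = ProviralElement("E", "".join(elem), (0, 300), (1700, 2000),
                                  100.0)
        locus = ProviralLocus("bad", "c", 4000, "+", "E",
                              frozenset({"pro", "pre"}), 0)
        panel = ReferencePanel({"c": host}, [element], [locus], "E")
        with pytest.raises(ContractViolation):
            predict_junction_fragment(locus, panel, (400, 432), BSRI)

    def test_no_host_cut_within_horizon_is_sentinel(self, rng):
        from ervscreen.synthetic_data import (
            ProviralElement, ProviralLocus, ReferencePanel, _scrub_motifs,
        )

        host = _scrub_motifs(random_dna(rng, 12000), ["ACTGG"], rng)
        elem = list(_scrub_motifs(random_dna(rng, 2000), ["ACTGG"], rng))
        elem[1500:1505] = "ACTGG"
        element = ProviralElement("E", "".join(elem), (0, 300), (1700, 2000),
                                  100.0)
        locus = ProviralLocus("far", "c", 6000, "+", "E",
                              frozenset({"pro", "pre"}), 0)
        panel = ReferencePanel({"c": host}, [element], [locus], "E")
        frag = predict_junction_fragment(locus, panel, (400, 432), BSRI)
        assert frag.size is None and not frag.detectable

    def test_oracle_equivalence_on_synthetic_panels(self, probe_interval):
        """Predicted sizes equal the composite-digest oracle exactly."""
        checked = 0
        for seed in (11, 23):
            panel = make_reference_panel(small_panel_config(seed=seed))
            for locus in panel.loci:
                frag = predict_junction_fragment(
                    locus, panel, probe_interval, BSRI, horizon=2500
                )
                want = oracle_junction_size(panel, locus, probe_interval,
                                            BSRI, flank=2500)
                assert frag.size == want, locus.locus_id
                checked += 1
        assert checked == 12

    def test_strand_mirror_same_size(self, small_panel, probe_interval):
        """A '-'-strand locus on the mirrored genome gives the same size."""
        from ervscreen.synthetic_data import ReferencePanel

        locus = next(l for l in small_panel.loci if l.strand == "+")
        host = small_panel.host_genome[locus.contig]
        mirrored = ReferencePanel(
            {locus.contig: revcomp(host)},
            small_panel.elements,
            [dataclasses.replace(locus, strand="-",
                                 insertion_point=len(host) - locus.insertion_point)],
            small_panel.reference_id,
        )
        a = predict_junction_fragment(locus, small_panel, probe_interval, BSRI)
        b = predict_junction_fragment(mirrored.loci[0], mirrored,
                                      probe_interval, BSRI)
        assert a.size == b.size

    def test_upstream_boundary_lies_in_host(self, small_panel, probe_interval):
        for locus in small_panel.loci:
            frag = predict_junction_fragment(locus, small_panel,
                                             probe_interval, BSRI)
            assert frag.detectable
            assert frag.upstream_cut is not None  # host-side boundary exists


class TestDigestPattern:
    def test_all_pre_individual_has_empty_pattern(self, small_panel, probe_seq):
        regions = {
            l.locus_id: (
                realize_haplotype(small_panel, l, "pre", flank=2500),
                realize_haplotype(small_panel, l, "pre", flank=2500),
            )
            for l in small_panel.loci
        }
        pat = digest_pattern(regions, BSRI, probe_seq, size_window=(1, 10**6))
        assert pat.sizes == ()

    def test_heterozygote_band_matches_prediction(
        self, small_panel, probe_interval, probe_seq
    ):
        locus = small_panel.loci[0]
        frag = predict_junction_fragment(locus, small_panel, probe_interval,
                                         BSRI, horizon=2500)
        regions = {
            locus.locus_id: (
                realize_haplotype(small_panel, locus, "pro", flank=2500),
                realize_haplotype(small_panel, locus, "pre", flank=2500),
            )
        }
        pat = digest_pattern(regions, BSRI, probe_seq, size_window=(1, 10**6))
        assert frag.size in pat.sizes

    def test_solo_haplotype_never_emits_band(self, small_panel, probe_seq):
        locus = small_panel.loci[0]
        assert "solo" in locus.repertoire
        regions = [realize_haplotype(small_panel, locus, "solo", flank=2500)]
        pat = digest_pattern(regions, BSRI, probe_seq, size_window=(1, 10**6))
        assert pat.sizes == ()

    def test_snp_destroying_host_cut_grows_band_to_next_cut(
        self, small_panel, probe_interval, probe_seq
    ):
        """Knocking out the upstream host site shifts the band to the next
        host cut; the mutated haplotype still matches the loop oracle."""
        locus = next(l for l in small_panel.loci if l.strand == "+")
        frag = predict_junction_fragment(locus, small_panel, probe_interval,
                                         BSRI, horizon=2500)
        hap = realize_haplotype(small_panel, locus, "pro", flank=2500)
        cut_in_hap = 2500 - (locus.insertion_point - frag.upstream_cut)
        # destroy the recognition site that produced the upstream cut
        site_starts = [cut_in_hap - BSRI.cut_offset,  # forward ACTGG
                       cut_in_hap - len(BSRI.site) + BSRI.cut_offset]  # CCAGT
        mutated = None
        for s in site_starts:
            window = hap[s : s + 5]
            if window in ("ACTGG", "CCAGT"):
                mutated = hap[:s] + ("T" if window == "ACTGG" else "A") \
                    + hap[s + 1 :]
                break
        assert mutated is not None, "upstream recognition site not located"
        pat = digest_pattern([mutated], BSRI, probe_seq,
                             size_window=(1, 10**6))
        cuts = oracle_cuts(mutated, BSRI)
        start = mutated.find(
            probe_seq if locus.strand == "+" else revcomp(probe_seq)
        )
        left = max(c for c in cuts if c <= start)
        right = min(c for c in cuts if c >= start + len(probe_seq))
        assert pat.sizes == (right - left,)
        assert right - left > frag.size

    def test_diploid_duplicate_sizes_collapse(self, small_panel, probe_seq):
        locus = small_panel.loci[0]
        hap = realize_haplotype(small_panel, locus, "pro", flank=2500)
        pat = digest_pattern([hap, hap], BSRI, probe_seq,
                             size_window=(1, 10**6))
        assert len(pat.sizes) == len(set(pat.sizes)) == 1
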