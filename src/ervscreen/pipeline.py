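"""End-to-end orchestration: simulate -> design probe -> predict fragments ->
virtual unblot -> PCR genotyping -> association, with one seed and one report.

All randomness derives from a single top-level seed fanned out per stage via
``numpy.random.SeedSequence(seed).spawn``-style child seeds, so each stage is
independently reproducible and identical configs yield identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .association_stats import association_scan, results_frame
from .band_analysis import (
    band_presence_counts,
    classify_clusters,
    cluster_frequencies,
    collate_bands,
)
from .errors import ConfigurationError, ErvScreenError
from .pcr_genotyping import carrier_table, design_primer_set, genotype_cohort
from .probe_design import find_conserved_window
from .synthetic_data import (
    CohortSpec,
    PanelConfig,
    ReferencePanel,
    element_rows,
    make_reference_panel,
    realize_genome,
    simulate_cohort,
)
from .virtual_digest import (
    BSRI,
    DEFAULT_ENZYMES,
    digest_pattern,
    predict_junction_fragment,
    select_enzymes,
)

log = logging.getLogger("ervscreen")


@dataclass
class RunConfig:
    """Everything a full pipeline run needs besides the seed."""

    panel: PanelConfig = field(default_factory=PanelConfig)
    cohort: CohortSpec | None = None  # None: demo frequencies are filled in
    probe_length: int = 32
    recent_k: int = 25
    max_ltr_distance: int = 2000
    enzyme_name: str = "BsrI"
    max_mismatch: int = 2
    size_window: tuple[int, int] = (500, 10000)
    rel_tolerance: float = 0.02
    pcr_size_tolerance: int = 50
    pcr_max_product: int = 5000
    alpha: float = 0.05
    horizon: int = 20000
    seed: int = 0


@dataclass
class RunReport:
    locus_table: pd.DataFrame  # per-locus joined view
    cluster_table: pd.DataFrame
    association: pd.DataFrame
    probe: str
    enzyme_name: str
    provenance: dict

    def body_text(self) -> str:
        """Canonical report body (provenance excluded) for determinism checks."""
        return (
            self.locus_table.to_csv(sep="\t", index=False)
            + "\n"
            + self.cluster_table.to_csv(sep="\t", index=False)
            + "\n"
            + self.association.to_csv(sep="\t", index=False)
            + f"\nprobe={self.probe}\nenzyme={self.enzyme_name}\n"
        )


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def demo_cohort_spec(panel: ReferencePanel, seed: int) -> CohortSpec:
    """A 25+25 cohort with a spread of realistic proviral allele frequencies,
    mirroring the mix of nearly fixed, common and rare polymorphic loci seen
    in screens of this kind."""
    base = [0.8, 0.5, 0.3, 0.15, 0.08, 0.6, 0.4, 0.25, 0.9, 0.12, 0.05, 0.7]
    freqs = {
        loc.locus_id: base[i % len(base)] for i, loc in enumerate(panel.loci)
    }
    return CohortSpec(n_cases=25, n_controls=25, frequencies=freqs,
                      snp_rate=0.0, seed=seed)


def build_resolvable_panel(
    config: PanelConfig,
    enzyme,
    probe_length: int,
    recent_k: int,
    max_ltr_distance: int,
    size_window: tuple[int, int],
    rel_tolerance: float,
    horizon: int,
    max_attempts: int = 25,
):
    """Generate a panel whose in-window junction fragments are band-resolvable.

    Enzyme selection in this kind of screen is driven by the predicted
    fragment-size distribution; analogously, the synthetic panel is
    regenerated (with a derived subseed) until no two in-window predicted
    fragments fall within 2.5x the band tolerance of each other, so each
    detectable locus owns an unambiguous band. Returns
    ``(panel, probe_candidate, predictions)``.
    """
    panel = make_reference_panel(config)
    rows = element_rows(panel)
    ref = panel.element(panel.reference_id)
    k = min(recent_k, len(rows) - 1)
    candidates = find_conserved_window(
        rows, panel.reference_id, ref.ltr5,
        recent_k=k, L=probe_length, max_ltr_distance=max_ltr_distance,
    )
    if not candidates:
        raise ConfigurationError("no conserved probe window found")
    probe_cand = candidates[0]
    probe_iv = (probe_cand.start, probe_cand.end)

    rng = np.random.default_rng([config.seed, 0x5EED])
    jitter = max(config.locus_spacing // 3, 1)
    contig_len = len(panel.host_genome[panel.loci[0].contig]) if panel.loci else 0
    accepted: list[float] = []
    predictions: dict[str, int] = {}
    new_loci = []
    for loc in panel.loci:
        placed = None
        for trial in range(max_attempts * 20):
            if trial == 0:
                cand = loc
            else:
                ip = int(loc.insertion_point + rng.integers(-jitter, jitter + 1))
                ip = min(max(ip, config.flank), contig_len - config.flank - 1)
                cand = replace(loc, insertion_point=ip)
            try:
                frag = predict_junction_fragment(
                    cand, panel, probe_iv, enzyme, horizon=horizon
                )
            except ErvScreenError:
                continue
            s = frag.size
            if s is None or not size_window[0] <= s <= size_window[1]:
                continue
            if all(abs(s - a) > 2.5 * rel_tolerance * max(s, a) for a in accepted):
                placed = (cand, s)
                break
        if placed is None:
            raise ConfigurationError(
                f"could not place locus {loc.locus_id} with a resolvable "
                f"in-window junction fragment"
            )
        new_loci.append(placed[0])
        accepted.append(placed[1])
        predictions[loc.locus_id] = placed[1]
    panel.loci = new_loci
    panel.validate()
    return panel, probe_cand, predictions


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    """Execute all stages in order; deterministic for a fixed config+seed."""
    seeds = _stage_seeds(config.seed)
    enzyme = next(
        (e for e in DEFAULT_ENZYMES if e.name == config.enzyme_name), BSRI
    )

    stage = "simulate-panel"
    try:
        panel_cfg = replace(config.panel, seed=seeds[0])
        panel, probe_cand, predictions = build_resolvable_panel(
            panel_cfg, enzyme, config.probe_length, config.recent_k,
            config.max_ltr_distance, config.size_window,
            config.rel_tolerance, config.horizon,
        )
        probe = probe_cand.sequence
        log.info("panel: %d elements, %d loci; probe %s at columns %d-%d",
                 len(panel.elements), len(panel.loci), probe,
                 probe_cand.start, probe_cand.end)

        stage = "select-enzyme"
        ref = panel.element(panel.reference_id)
        eligible = select_enzymes(ref.seq, ref.ltr5, DEFAULT_ENZYMES)
        if enzyme.name not in [e.name for e in eligible]:
            raise ConfigurationError(
                f"{enzyme.name} does not satisfy the cut-in-body/"
                f"no-cut-in-5'LTR constraint on the reference element"
            )

        stage = "simulate-cohort"
        cohort_spec = config.cohort or demo_cohort_spec(panel, seeds[1])
        cohort_spec = replace(cohort_spec, seed=seeds[1])
        cohort = simulate_cohort(panel, cohort_spec)
        groups = {ind.individual_id: ind.group for ind in cohort}
        log.info("cohort: %d cases + %d controls",
                 cohort_spec.n_cases, cohort_spec.n_controls)

        stage = "realize-genomes"
        flank = config.panel.flank
        regions = {
            ind.individual_id: realize_genome(
                ind, panel, flank=flank,
                snp_rate=cohort_spec.snp_rate, seed=seeds[2],
            )
            for ind in cohort
        }

        stage = "unblot"
        patterns = [
            digest_pattern(
                regions[ind.individual_id], enzyme, probe,
                max_mismatch=config.max_mismatch,
                size_window=config.size_window,
                individual_id=ind.individual_id, group=ind.group,
            )
            for ind in cohort
        ]

        stage = "pcr"
        primer_sets = {
            loc.locus_id: design_primer_set(
                panel, loc, flank=flank, max_product=config.pcr_max_product
            )
            for loc in panel.loci
        }
        calls = genotype_cohort(
            cohort, panel, primer_sets, regions,
            size_tolerance=config.pcr_size_tolerance,
            max_product=config.pcr_max_product,
        )
        pcr_df = carrier_table(calls, groups)
        pcr_carriers = {
            ind.individual_id: {
                c.locus_id: c.carrier for c in calls
                if c.individual_id == ind.individual_id
            }
            for ind in cohort
        }

        stage = "collate-bands"
        clusters = collate_bands(patterns, config.rel_tolerance)
        classify_clusters(
            clusters, predictions, pcr_carriers, config.rel_tolerance,
            all_individuals=[ind.individual_id for ind in cohort],
        )
        cluster_df = cluster_frequencies(clusters, groups)
        presence_df = band_presence_counts(
            patterns, predictions, config.rel_tolerance
        )

        stage = "assoc"
        assoc = association_scan(pcr_df, alpha=config.alpha)
        assoc_df = results_frame(assoc)

        stage = "join"
        locus_df = pcr_df.rename(
            columns={"case_pos": "pcr_case_pos", "control_pos": "pcr_control_pos"}
        ).merge(
            presence_df.rename(
                columns={"case_pos": "band_case_pos",
                         "control_pos": "band_control_pos"}
            ),
            on="locus_id", how="left",
        )
        locus_df["predicted_bp"] = locus_df["locus_id"].map(predictions)
        locus_df["in_window"] = locus_df["predicted_bp"].apply(
            lambda s: s is not None
            and config.size_window[0] <= s <= config.size_window[1]
        )
        locus_df = locus_df.merge(
            assoc_df[["site_id", "chi2", "p", "significant", "monomorphic"]],
            left_on="locus_id", right_on="site_id", how="left",
        ).drop(columns=["site_id"])
    except ErvScreenError as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    provenance = {
        "seed": config.seed,
        "version": __version__,
        "config_hash": _config_hash(config),
        "n_loci": len(panel.loci),
        "n_individuals": len(cohort),
    }
    report = RunReport(locus_df, cluster_df, assoc_df, probe, enzyme.name,
                       provenance)
    if outdir is not None:
        _write_outputs(Path(outdir), report, panel, cohort, primer_sets,
                       patterns)
    return report


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_outputs(outdir, report, panel, cohort, primer_sets, patterns):
    from . import io as eio

    outdir.mkdir(parents=True, exist_ok=True)
    eio.write_panel(outdir / "panel", panel)
    eio.write_genotype_matrix(outdir / "genotypes.tsv", cohort, panel.loci)
    eio.write_primer_table(outdir / "primers.tsv", primer_sets)
    band_rows = [
        {"individual_id": p.individual_id, "group": p.group,
         "bands": ",".join(map(str, p.sizes))}
        for p in patterns
    ]
    eio.write_tsv(outdir / "bands.tsv", pd.DataFrame(band_rows))
    eio.write_tsv(outdir / "locus_report.tsv", report.locus_table)
    eio.write_tsv(outdir / "cluster_report.tsv", report.cluster_table)
    eio.write_tsv(outdir / "association.tsv", report.association)
    (outdir / "provenance.json").write_text(
        json.dumps(report.provenance, indent=2) + "\n"
    )
    (outdir / "probe.fasta").write_text(f">probe\n{report.probe}\n")
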