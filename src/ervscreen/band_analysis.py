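"""Cross-cohort collation of band patterns and novel-band flagging.

Lanes from different individuals are compared by clustering band sizes with
a scale-relative tolerance (single linkage on log size), matching how bands
are visually aligned across lanes on a gel. Each cluster is then classified
against the in silico predicted junction-fragment sizes of known loci and,
when available, the PCR carrier calls: a cluster is assigned to a known
locus only when both its size and its presence/absence distribution across
individuals agree — the dual-evidence rule of the screen. Size-matched
clusters with discordant distributions, or sizes matched by two
predictions, stay ambiguous; everything else is a putatively novel
polymorphic insertion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, DataError


@dataclass(frozen=True)
class BandPattern:
    """One lane: the set of detected fragment sizes for one individual."""

    individual_id: str
    group: str
    sizes: tuple[int, ...]  # bp, sorted descending


@dataclass
class BandCluster:
    """A cross-cohort cluster of size-matched bands."""

    representative: float  # median member size, bp
    members: list[tuple[str, int]]  # (individual_id, size)
    classification: str = "unclassified"  # known | novel | ambiguous
    locus_id: str | None = None
    wide: bool = False  # span exceeds 2x tolerance (possible chaining)

    @property
    def present_individuals(self) -> frozenset[str]:
        return frozenset(ind for ind, _ in self.members)


def collate_bands(
    patterns: Sequence[BandPattern], rel_tolerance: float = 0.02
) -> list[BandCluster]:
    """Single-linkage clustering of all bands on log size.

    Two bands link when their sizes differ by at most ``rel_tolerance``
    (relative); clusters are the connected runs of the sorted size list.
    Every input band lands in exactly one cluster. Clusters whose total
    span exceeds twice the tolerance are flagged ``wide`` (chaining).
    """
    if not 0.0 < rel_tolerance <= 0.2:
        raise ConfigurationError("rel_tolerance must be in (0, 0.2]")
    bands = [
        (size, pat.individual_id) for pat in patterns for size in pat.sizes
    ]
    if not bands:
        return []
    bands.sort()
    gap = math.log1p(rel_tolerance)
    clusters: list[BandCluster] = []
    run: list[tuple[int, str]] = [bands[0]]
    for prev, cur in zip(bands, bands[1:]):
        if math.log(cur[0]) - math.log(prev[0]) <= gap:
            run.append(cur)
        else:
            clusters.append(_finalize(run, rel_tolerance))
            run = [cur]
    clusters.append(_finalize(run, rel_tolerance))
    return clusters


def _finalize(run: list[tuple[int, str]], rel_tolerance: float) -> BandCluster:
    sizes = sorted(s for s, _ in run)
    n = len(sizes)
    median = (sizes[n // 2] if n % 2 else (sizes[n // 2 - 1] + sizes[n // 2]) / 2)
    span = math.log(sizes[-1]) - math.log(sizes[0])
    return BandCluster(
        representative=float(median),
        members=sorted((ind, s) for s, ind in run),
        wide=span > 2 * math.log1p(rel_tolerance),
    )


def classify_clusters(
    clusters: Sequence[BandCluster],
    predictions: Mapping[str, float],
    pcr_calls: Mapping[str, Mapping[str, bool]] | None = None,
    rel_tolerance: float = 0.02,
    all_individuals: Sequence[str] | None = None,
) -> list[BandCluster]:
    """Annotate clusters as known(locus) / novel / ambiguous, in place.

    ``predictions`` maps locus_id -> predicted junction-fragment size;
    ``pcr_calls`` maps individual -> locus -> carrier flag. A cluster is
    known(locus) when exactly one predicted size matches its representative
    within tolerance and (when PCR calls are supplied) its presence vector
    equals the locus's PCR carrier vector over all individuals; size match
    with a discordant vector, or two matching predictions, is ambiguous.
    """
    if pcr_calls is not None and all_individuals is None:
        all_individuals = sorted(pcr_calls)
    for cl in clusters:
        matches = [
            lid
            for lid, size in predictions.items()
            if size is not None
            and abs(cl.representative - size) <= rel_tolerance * size
        ]
        if not matches:
            cl.classification, cl.locus_id = "novel", None
        elif len(matches) > 1:
            cl.classification, cl.locus_id = "ambiguous", None
        else:
            lid = matches[0]
            if pcr_calls is None:
                cl.classification, cl.locus_id = "known", lid
            else:
                present = cl.present_individuals
                concordant = all(
                    (ind in present) == bool(pcr_calls[ind][lid])
                    for ind in all_individuals
                )
                if concordant:
                    cl.classification, cl.locus_id = "known", lid
                else:
                    cl.classification, cl.locus_id = "ambiguous", lid
    return list(clusters)


def cluster_frequencies(
    clusters: Sequence[BandCluster], groups: Mapping[str, str]
) -> pd.DataFrame:
    """Per-cluster 2x2 counts: individuals with >= 1 member band, by group.

    ``groups`` maps every individual in the cohort (including band-free
    lanes) to 'case' or 'control'; group sizes are taken from it.
    """
    bad = set(groups.values()) - {"case", "control"}
    if bad:
        raise DataError(f"unknown group labels {sorted(bad)}")
    n_cases = sum(1 for g in groups.values() if g == "case")
    n_controls = len(groups) - n_cases
    rows = []
    for cl in clusters:
        unlabeled = cl.present_individuals - set(groups)
        if unlabeled:
            raise DataError(f"individuals without group label: {sorted(unlabeled)}")
        case_pos = sum(1 for i in cl.present_individuals if groups[i] == "case")
        ctrl_pos = len(cl.present_individuals) - case_pos
        rows.append(
            {
                "representative_bp": cl.representative,
                "classification": cl.classification,
                "locus_id": cl.locus_id,
                "case_pos": case_pos,
                "case_n": n_cases,
                "control_pos": ctrl_pos,
                "control_n": n_controls,
                "case_freq": case_pos / n_cases if n_cases else float("nan"),
                "control_freq": ctrl_pos / n_controls if n_controls else float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "representative_bp", "classification", "locus_id",
            "case_pos", "case_n", "control_pos", "control_n",
            "case_freq", "control_freq",
        ],
    )


def band_presence_counts(
    patterns: Sequence[BandPattern],
    predictions: Mapping[str, float],
    rel_tolerance: float = 0.02,
) -> pd.DataFrame:
    """Per-locus presence counts: individuals with a band at the predicted size.

    The direct per-locus view of the band data (bypassing clustering), used
    for cross-checking band presence against PCR carrier counts.
    """
    rows = []
    for lid, size in predictions.items():
        if size is None:
            continue
        tol = rel_tolerance * size
        pos = {"case": 0, "control": 0}
        for pat in patterns:
            if any(abs(s - size) <= tol for s in pat.sizes):
                pos[pat.group] += 1
        rows.append({"locus_id": lid, "predicted_bp": size,
                     "case_pos": pos["case"], "control_pos": pos["control"]})
    return pd.DataFrame(rows, columns=["locus_id", "predicted_bp",
                                       "case_pos", "control_pos"])
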