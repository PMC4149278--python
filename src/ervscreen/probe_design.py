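"""Probe selection from an identity-ranked proviral alignment.

The screen's hybridization probe is a short window in the *gag* leader,
chosen to be (1) highly conserved among the most recently integrated
elements, (2) distinct from the older elements, and (3) proximal to, but
strictly outside, the 5'LTR — so the probe lights up the host/provirus
junction fragment of every recent insertion while ignoring the old, fixed
proviral background.

Scoring (declared here, since no canonical formula exists):

* recent conservation = mean pairwise identity over the window among the
  ``recent_k`` elements closest to the reference;
* distinctness = the maximum identity between the recent-subset consensus of
  the window and any older element (lower is better).

``probe_hits`` is an ungapped k-mismatch scan over both strands —
substitutions only, which suits a ~32 nt probe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._seq import as_u8, mismatch_profile, revcomp
from .errors import ConfigurationError


@dataclass(frozen=True)
class ProbeCandidate:
    """A fixed-length alignment window scored as a probe candidate."""

    sequence: str  # recent-subset consensus over the window
    start: int  # alignment column interval [start, end)
    end: int
    recent_score: float  # mean pairwise identity within the recent subset
    older_max_identity: float  # max identity vs any older element
    ltr_distance: int  # bp from the 3' end of the 5'LTR to the window start


@dataclass(frozen=True)
class ProbeHit:
    contig: str
    start: int  # 0-based top-strand position of the leftmost matched base
    strand: str
    mismatches: int

    @property
    def key(self):
        return (self.contig, self.start, self.strand)


def pairwise_identity(row_a: str, row_b: str) -> float:
    """Percent identity over columns where neither row has a gap."""
    if len(row_a) != len(row_b):
        raise ValueError("rows must be equal-length (aligned)")
    a, b = as_u8(row_a), as_u8(row_b)
    gap = ord("-")
    shared = (a != gap) & (b != gap)
    n = int(shared.sum())
    if n == 0:
        return 0.0
    return 100.0 * float((a[shared] == b[shared]).sum()) / n


def rank_by_identity(
    rows: Mapping[str, str], reference_id: str
) -> list[tuple[str, float]]:
    """Elements ordered by decreasing percent identity to the reference.

    Ties break on element id, so the order is invariant under input
    shuffling; the reference itself sorts first at 100%.
    """
    if reference_id not in rows:
        raise KeyError(f"reference element {reference_id!r} not in input")
    ref = rows[reference_id]
    scored = [
        (eid, pairwise_identity(ref, seq)) for eid, seq in rows.items()
    ]
    scored.sort(key=lambda t: (t[0] != reference_id, -t[1], t[0]))
    return scored


def _consensus(mat: np.ndarray) -> np.ndarray:
    """Column-wise majority symbol; ties resolve to the smallest byte value."""
    ncol = mat.shape[1]
    out = np.empty(ncol, dtype=np.uint8)
    for j in range(ncol):
        vals, counts = np.unique(mat[:, j], return_counts=True)
        out[j] = vals[np.argmax(counts)]
    return out


def find_conserved_window(
    rows: Mapping[str, str],
    reference_id: str,
    ltr5: tuple[int, int],
    recent_k: int = 25,
    L: int = 32,
    max_ltr_distance: int = 2000,
) -> list[ProbeCandidate]:
    """Score every length-``L`` window 3' of the 5'LTR as a probe candidate.

    ``ltr5`` is the 5'LTR interval in alignment columns. Candidates are
    ranked by (recent conservation desc, older max identity asc, LTR
    distance asc), ties broken by leftmost column. Windows whose
    recent-subset consensus contains a gap are skipped. Returns all
    qualifying windows, best first; empty list when none qualify.
    """
    if L < 8:
        raise ConfigurationError("window length L must be >= 8")
    if recent_k >= len(rows):
        raise ConfigurationError("recent_k must be smaller than the row count")
    order = [eid for eid, _ in rank_by_identity(rows, reference_id)]
    recent_ids, older_ids = order[:recent_k], order[recent_k:]
    ncol = len(rows[reference_id])
    lo = ltr5[1]
    hi = min(ncol, ltr5[1] + max_ltr_distance)
    if hi - lo < L:
        return []

    mat = np.vstack([as_u8(rows[eid]) for eid in order])
    recent = mat[:recent_k]
    older = mat[recent_k:]
    gap = ord("-")

    # per-column pairwise match fraction within the recent subset, via all
    # unordered pairs; window score is the mean over its columns
    iu, ju = np.triu_indices(recent_k, k=1)
    pair_match = (recent[iu] == recent[ju]).mean(axis=0)  # (ncol,)
    cons = _consensus(recent)
    older_match = (older == cons) if older.size else np.zeros((0, ncol), bool)

    def window_mean(arr: np.ndarray, s: int) -> float:
        return float(arr[s : s + L].mean())

    cands = []
    for s in range(lo, hi - L + 1):
        win_cons = cons[s : s + L]
        if gap in win_cons:
            continue
        recent_score = window_mean(pair_match, s)
        if older_match.shape[0]:
            older_max = float(older_match[:, s : s + L].mean(axis=1).max())
        else:
            older_max = 0.0
        cands.append(
            ProbeCandidate(
                sequence=win_cons.tobytes().decode("ascii"),
                start=s,
                end=s + L,
                recent_score=recent_score,
                older_max_identity=older_max,
                ltr_distance=s - ltr5[1],
            )
        )
    cands.sort(
        key=lambda c: (-c.recent_score, c.older_max_identity, c.ltr_distance, c.start)
    )
    return cands


def probe_hits(
    probe: str,
    genome: Mapping[str, str] | str,
    max_mismatch: int = 2,
) -> list[ProbeHit]:
    """All ungapped matches of ``probe`` on either strand of ``genome``.

    Hamming distance <= ``max_mismatch``; hit start is the top-strand
    coordinate of the leftmost matched base regardless of strand.
    """
    if len(probe) < 8:
        raise ConfigurationError("probe must be at least 8 nt")
    if max_mismatch < 0:
        raise ConfigurationError("max_mismatch must be >= 0")
    if isinstance(genome, str):
        genome = {"seq": genome}
    rc = revcomp(probe)
    hits: list[ProbeHit] = []
    for contig, seq in genome.items():
        for strand, pat in (("+", probe), ("-", rc)):
            prof = mismatch_profile(seq, pat)
            for pos in np.flatnonzero(prof <= max_mismatch):
                hits.append(ProbeHit(contig, int(pos), strand, int(prof[pos])))
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits
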