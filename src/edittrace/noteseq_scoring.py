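"""Scoring of in-vitro cleavage (ONE-seq-style) panel observations.

Each sequenced cleaved-half read is reduced upstream to a barcode-resolved
site identity plus a signed ``cut_offset`` (nucleotides from the expected cut
reference point, negative toward the PAM).  Reads are accepted within a fixed
cleavage-site window, pooled over replicates per RNP:DNA condition, and each
site is scored as its accepted count divided by the on-target count.  A site
is called an off-target when either condition's count exceeds an absolute
background, estimated as max(a read floor, the plateau of the ranked count
curve).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

CONDITIONS = ("ratio_10_1", "ratio_1_1")
UNASSIGNED = "__unassigned__"

DEFAULT_WINDOW_PAM = 6
DEFAULT_WINDOW_PROTO = 8
DEFAULT_FLOOR = 10
DEFAULT_PLATEAU_WINDOW = 25
DEFAULT_PLATEAU_SLOPE_TOL = 0.05
# expected cut reference: after protospacer base 18 (distal staggered cut)
DEFAULT_CUT_POSITION = 18


@dataclass
class NoteSeqResult:
    site_id: str
    count_10: int
    count_1: int
    background: int
    score_10: float  # NaN when the condition's on-target count is zero
    score_1: float
    is_off_target: bool


def accept_cleavage(
    observations: pd.DataFrame,
    barcode_map: pd.DataFrame | None = None,
    window_pam: int = DEFAULT_WINDOW_PAM,
    window_proto: int = DEFAULT_WINDOW_PROTO,
) -> pd.DataFrame:
    """Accept observations inside the cleavage window and pool replicates.

    ``observations`` needs columns ``condition``, ``replicate``, ``cut_offset``
    and either ``site_id`` or barcode columns (``barcode_left``,
    ``barcode_right``) resolved through ``barcode_map``.  An optional
    ``count`` column carries pre-aggregated read counts (default 1 per row).
    Returns a tidy frame (site_id, condition, accepted, rejected); reads with
    an unresolvable barcode pair are pooled under the ``__unassigned__``
    site_id, never dropped.
    """
    obs = observations.copy()
    if "count" not in obs.columns:
        obs["count"] = 1
    if "site_id" not in obs.columns:
        if barcode_map is None:
            raise ValueError("observations lack site_id and no barcode_map given")
        keyed = barcode_map.set_index(["barcode_left", "barcode_right"])["site_id"]
        pairs = pd.MultiIndex.from_frame(obs[["barcode_left", "barcode_right"]])
        obs["site_id"] = keyed.reindex(pairs).fillna(UNASSIGNED).to_numpy()
    accepted_mask = (obs["cut_offset"] >= -window_pam) & (obs["cut_offset"] <= window_proto)
    obs["accepted"] = np.where(accepted_mask, obs["count"], 0)
    obs["rejected"] = np.where(accepted_mask, 0, obs["count"])
    out = (
        obs.groupby(["site_id", "condition"], as_index=False)[["accepted", "rejected"]]
        .sum()
        .sort_values(["site_id", "condition"], ignore_index=True)
    )
    return out


def estimate_background(
    counts,
    floor: int = DEFAULT_FLOOR,
    plateau_window: int = DEFAULT_PLATEAU_WINDOW,
    plateau_slope_tol: float = DEFAULT_PLATEAU_SLOPE_TOL,
) -> int:
    """Estimate the absolute read background from per-site total counts.

    Counts are ranked in descending order; the plateau is the first run of
    ``plateau_window`` consecutive sites whose relative change per step is
    below ``plateau_slope_tol``, and its mean is the plateau value.  Returns
    max(floor, rounded plateau value); the floor alone when no plateau exists
    or there are too few sites.
    """
    arr = np.sort(np.asarray(list(counts), dtype=float))[::-1]
    if arr.size < plateau_window:
        warnings.warn(
            f"only {arr.size} sites (< plateau window {plateau_window}); using floor {floor}",
            stacklevel=2,
        )
        return floor
    prev = arr[:-1]
    nxt = arr[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(prev - nxt) / prev
    rel[(prev == 0) & (nxt == 0)] = 0.0
    rel[(prev == 0) & (nxt != 0)] = np.inf
    flat = rel < plateau_slope_tol
    run = plateau_window - 1  # steps inside a window of plateau_window sites
    for start in range(flat.size - run + 1):
        if flat[start : start + run].all():
            plateau = float(arr[start : start + plateau_window].mean())
            return max(floor, int(round(plateau)))
    return floor


def score_and_call(
    counts: pd.DataFrame,
    on_target_id: str,
    background: int,
    site_loci: dict[str, list[str]] | None = None,
) -> list[NoteSeqResult]:
    """Score sites against the on-target and call off-targets above background.

    ``counts`` is the accepted-count frame from :func:`accept_cleavage`.
    Scores are per condition: site count / on-target count; a zero on-target
    count leaves that condition's scores undefined (NaN) and calls fall back
    to the other condition.  A site is an off-target when either condition's
    count strictly exceeds ``background`` for at least one of its genomic
    loci (``site_loci`` maps a site to its loci; by default each site is its
    own single locus).  The on-target itself is never called.
    """
    wide = (
        counts[counts["site_id"] != UNASSIGNED]
        .pivot_table(index="site_id", columns="condition", values="accepted", fill_value=0)
        .reindex(columns=list(CONDITIONS), fill_value=0)
    )
    if on_target_id not in wide.index:
        raise ValueError(f"on-target site {on_target_id!r} absent from counts")
    on10 = float(wide.loc[on_target_id, "ratio_10_1"])
    on1 = float(wide.loc[on_target_id, "ratio_1_1"])
    if on10 == 0:
        warnings.warn("zero on-target count in 10:1 condition; its scores are undefined", stacklevel=2)
    if on1 == 0:
        warnings.warn("zero on-target count in 1:1 condition; its scores are undefined", stacklevel=2)

    locus_pass: dict[str, bool] = {}
    for site_id, row in wide.iterrows():
        c10, c1 = int(row["ratio_10_1"]), int(row["ratio_1_1"])
        above10 = c10 > background if on10 > 0 else False
        above1 = c1 > background if on1 > 0 else False
        if on10 == 0 and on1 == 0:  # no usable condition: no calls at all
            above10 = above1 = False
        locus_pass[site_id] = above10 or above1

    results = []
    for site_id, row in wide.iterrows():
        c10, c1 = int(row["ratio_10_1"]), int(row["ratio_1_1"])
        loci = (site_loci or {}).get(site_id, [site_id])
        called = site_id != on_target_id and any(locus_pass.get(l, locus_pass[site_id]) for l in loci)
        results.append(
            NoteSeqResult(
                site_id=site_id,
                count_10=c10,
                count_1=c1,
                background=background,
                score_10=c10 / on10 if on10 > 0 else float("nan"),
                score_1=c1 / on1 if on1 > 0 else float("nan"),
                is_off_target=called,
            )
        )
    results.sort(key=lambda r: r.site_id)
    return results


def results_table(results: list[NoteSeqResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [r.site_id for r in results],
            "count_10": [r.count_10 for r in results],
            "count_1": [r.count_1 for r in results],
            "score_10": [r.score_10 for r in results],
            "score_1": [r.score_1 for r in results],
            "background": [r.background for r in results],
            "is_off_target": [r.is_off_target for r in results],
        }
    )
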