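"""Dyad-level aggregate indices.

Individual measures are aggregated within each dyad into:

* *intensity* indices — the dyadic mean of ratings (valence, arousal)
  and physiology (mean IBI, respiratory rate, SC level);
* *dissimilarity* indices — the absolute within-dyad rating difference;
* *mutual* indices — the product of the two members' scores
  (connectedness per video; social identification and desire for future
  interactions at t0/t1, with the t1 − t0 change in the product as the
  bonding change score), which rewards both intensity and reciprocity:
  for a fixed sum a + b the product a·b is maximal when a = b;
* *neutral-baseline corrections* — per dyad, the positive-video and
  negative-video rows minus the neutral-video row, isolating the change
  attributable to the emotional manipulation.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import DyadSession

# columns that are per-(dyad, video) measurements and hence baseline-correctable
CORRECTABLE_PREFIXES = ("dyadic_mean_", "dyadic_diff_", "mutual_connectedness",
                        "synchrony_")
METADATA_COLUMNS = ("dyad", "attention", "video", "condition")


def _require_present(*values):
    for v in values:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError("missing member value; dyadic indices are never imputed")


def dyadic_mean(a: float, b: float) -> float:
    """Within-dyad average (index of intensity)."""
    _require_present(a, b)
    return (a + b) / 2.0


def dyadic_abs_difference(a: float, b: float) -> float:
    """Within-dyad absolute difference (index of dissimilarity)."""
    _require_present(a, b)
    return abs(a - b)


def mutual_product(a: float, b: float) -> float:
    """Product of the members' scores (index of mutuality/reciprocity)."""
    _require_present(a, b)
    return a * b


def change_score(product_t1: float, product_t0: float) -> float:
    """t1 − t0 change in a mutual product; positive = attitudes increased."""
    _require_present(product_t1, product_t0)
    return product_t1 - product_t0


def build_index_table(sessions: Sequence[DyadSession],
                      synchrony_table: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """One row per dyad × video of aggregate indices.

    Rating-based indices come from the session rating tables
    (connectedness is each member's mean over the four items *before*
    the product is taken); physiological means come from the generating
    ground truth when present.  ``synchrony_table`` (columns
    ``dyad, video, channel, band, value``) is pivoted into
    ``synchrony_<channel>_<band>`` columns and joined.
    """
    rows = []
    for session in sessions:
        ratings = session.ratings
        att = session.attitudes
        mutual_ident_change = change_score(
            mutual_product(att.loc[0, "identification_t1"], att.loc[1, "identification_t1"]),
            mutual_product(att.loc[0, "identification_t0"], att.loc[1, "identification_t0"]))
        mutual_desire_change = change_score(
            mutual_product(att.loc[0, "desire_t1"], att.loc[1, "desire_t1"]),
            mutual_product(att.loc[0, "desire_t0"], att.loc[1, "desire_t0"]))
        for v, cond in enumerate(session.video_conditions):
            r = ratings[ratings["video"] == v].set_index("member")
            row = {
                "dyad": session.dyad_id,
                "attention": session.attention,
                "video": v,
                "condition": cond,
                "dyadic_mean_valence": dyadic_mean(r.loc[0, "valence"], r.loc[1, "valence"]),
                "dyadic_mean_arousal": dyadic_mean(r.loc[0, "arousal"], r.loc[1, "arousal"]),
                "dyadic_diff_valence": dyadic_abs_difference(r.loc[0, "valence"],
                                                             r.loc[1, "valence"]),
                "dyadic_diff_arousal": dyadic_abs_difference(r.loc[0, "arousal"],
                                                             r.loc[1, "arousal"]),
                "dyadic_mean_connectedness": dyadic_mean(r.loc[0, "connectedness"],
                                                         r.loc[1, "connectedness"]),
                "mutual_connectedness": mutual_product(r.loc[0, "connectedness"],
                                                       r.loc[1, "connectedness"]),
                "mutual_identification_change": mutual_ident_change,
                "mutual_desire_change": mutual_desire_change,
            }
            physio = _physio_means(session, v)
            row.update(physio)
            rows.append(row)
    table = pd.DataFrame(rows)
    if synchrony_table is not None and len(synchrony_table):
        wide = synchrony_table.copy()
        wide["col"] = ("synchrony_" + wide["channel"].astype(str)
                       + "_" + wide["band"].astype(str))
        wide = wide.pivot_table(index=["dyad", "video"], columns="col",
                                values="value").reset_index()
        table = table.merge(wide, on=["dyad", "video"], how="left")
    return table


def _physio_means(session: DyadSession, video: int) -> dict:
    out = {}
    vals = {"ibi_ms": [], "rsp_rate": [], "sc_level": []}
    for m in range(2):
        mv = session.data.get((m, video))
        if mv is None:
            return out
        if "mean_ibi_ms" in mv.truth:
            vals["ibi_ms"].append(mv.truth["mean_ibi_ms"])
        if "expiration_onsets_s" in mv.truth:
            dur_min = session.config.duration_s / 60.0 if session.config else 5.0
            vals["rsp_rate"].append(len(mv.truth["expiration_onsets_s"]) / dur_min)
        if "sc" in mv.recordings:
            vals["sc_level"].append(float(mv.recordings["sc"].samples.mean()))
    for key, pair in vals.items():
        if len(pair) == 2:
            out[f"dyadic_mean_{key}"] = dyadic_mean(*pair)
    return out


def neutral_baseline_correct(table: pd.DataFrame,
                             columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Subtract each dyad's neutral-video row from its emotional-video rows.

    Returns two rows per complete dyad (positive − neutral and
    negative − neutral) for every correctable column; attention and
    presentation-order metadata are carried through unchanged.  Dyads
    without a neutral-video row are dropped (never imputed).
    """
    if columns is None:
        columns = [c for c in table.columns
                   if any(c.startswith(p) for p in CORRECTABLE_PREFIXES)]
    out_rows = []
    for dyad, grp in table.groupby("dyad", sort=True):
        by_cond = {row["condition"]: row for _, row in grp.iterrows()}
        if "neutral" not in by_cond:
            continue
        base = by_cond["neutral"]
        for cond in ("positive", "negative"):
            if cond not in by_cond:
                continue
            row = by_cond[cond]
            corrected = {
                "dyad": dyad,
                "attention": row["attention"],
                "condition": cond,
                "video": row["video"],
            }
            for col in columns:
                if col in row.index and pd.notna(row[col]) and pd.notna(base[col]):
                    corrected[col] = row[col] - base[col]
                else:
                    corrected[col] = np.nan
            for col in row.index:
                if col not in corrected and col not in columns:
                    corrected[col] = row[col]
            out_rows.append(corrected)
    return pd.DataFrame(out_rows)
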