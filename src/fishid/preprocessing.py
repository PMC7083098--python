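"""Trait transformations taking raw open-field-trial records to analysis scale.

The analysis scale is reached in a fixed order:

1. tracklength (cm) is converted to body lengths using the *species mean*
   standard length (mm) — individual lengths are deliberately not used, so
   size-dependent among-individual variation is retained within species;
2. time-in-middle (s) is square-root transformed toward residual normality;
3. all four traits are mean-centred and scaled to standard deviation units
   (SDU) using the *global* mean and SD, pooled over every observation of
   every species, so species mean differences survive standardization.

Activity and area covered (percentages) pass through steps 1–2 unchanged, so
the order of those steps is immaterial for them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference_tables import TRAITS

#: Raw column names of a trial table, in schema order.
RAW_COLUMNS = [
    "species", "fish_id", "group", "order_in_group", "repeat",
    "tl_cm", "act_pct", "ac_pct", "tim_s", "sl_mm",
]


def to_body_lengths(tl_cm, species_mean_sl_mm):
    """Convert a tracklength in cm to multiples of the species mean SL (mm).

    Parameters
    ----------
    tl_cm : array_like
        Tracklength(s) in centimetres.
    species_mean_sl_mm : float
        Species mean standard length in millimetres; must be positive.
    """
    sl = float(species_mean_sl_mm)
    if not sl > 0:
        raise ValueError(f"species mean standard length must be > 0, got {sl}")
    return np.multiply(tl_cm, 10.0) / sl


def transform_tim(tim_s):
    """Square-root transform of time-in-middle (seconds, non-negative)."""
    tim = np.asarray(tim_s, dtype=float)
    if np.any(tim < 0):
        raise ValueError("time-in-middle must be non-negative")
    return np.sqrt(tim)


@dataclass
class ScalingRecord:
    """Global standardization constants enabling an exact inverse transform."""

    means: dict = field(default_factory=dict)   # trait -> pooled mean
    sds: dict = field(default_factory=dict)     # trait -> pooled sample SD
    species_mean_sl: dict = field(default_factory=dict)  # species -> SL (mm)

    def save(self, path):
        Path(path).write_text(json.dumps(
            {"means": self.means, "sds": self.sds,
             "species_mean_sl": self.species_mean_sl}, indent=1))

    @classmethod
    def load(cls, path):
        d = json.loads(Path(path).read_text())
        return cls(d["means"], d["sds"], d["species_mean_sl"])


def global_standardize(table: pd.DataFrame, traits=TRAITS):
    """Mean-centre and scale trait columns to global SD units.

    Statistics are computed on trial-level observations pooled across all
    species.  Returns the standardized table and the :class:`ScalingRecord`
    needed to invert the transform.
    """
    out = table.copy()
    rec = ScalingRecord()
    for t in traits:
        col = out[t].to_numpy(dtype=float)
        if col.size < 2:
            raise ValueError(f"trait {t!r}: need at least 2 observations")
        m = col.mean()
        s = col.std(ddof=1)
        if not s > 0:
            raise ValueError(f"trait {t!r} has zero variance; cannot standardize")
        out[t] = (col - m) / s
        rec.means[t] = float(m)
        rec.sds[t] = float(s)
    return out, rec


def inverse_standardize(table: pd.DataFrame, record: ScalingRecord,
                        traits=TRAITS) -> pd.DataFrame:
    """Undo :func:`global_standardize` using its :class:`ScalingRecord`."""
    out = table.copy()
    for t in traits:
        out[t] = out[t] * record.sds[t] + record.means[t]
    return out


def preprocess(raw: pd.DataFrame, species_mean_sl: dict | None = None,
               standardize: bool = True):
    """Full raw-to-analysis transformation of a trial table.

    Parameters
    ----------
    raw : DataFrame
        Table in the :data:`RAW_COLUMNS` schema.
    species_mean_sl : dict, optional
        Species -> mean SL (mm).  Defaults to the per-species ``sl_mm``
        column (which is constant within species by construction).
    standardize : bool
        If False, stop after the body-length and square-root steps (trait
        columns are then on the generator's analysis scale but not SDU).

    Returns
    -------
    (DataFrame, ScalingRecord or None)
        Table with trait columns TL, Act, AC, TIM replacing the raw measures.
    """
    out = raw.copy()
    if species_mean_sl is None:
        sl_by_species = raw.groupby("species")["sl_mm"].first().to_dict()
    else:
        sl_by_species = dict(species_mean_sl)
    tl = np.empty(len(out))
    for sp, idx in out.groupby("species").groups.items():
        tl[out.index.get_indexer(idx)] = to_body_lengths(
            out.loc[idx, "tl_cm"].to_numpy(), sl_by_species[sp])
    out["TL"] = tl
    out["Act"] = out["act_pct"].astype(float)
    out["AC"] = out["ac_pct"].astype(float)
    out["TIM"] = transform_tim(out["tim_s"].to_numpy())
    out = out[["species", "fish_id", "group", "order_in_group", "repeat"] + TRAITS]
    if not standardize:
        return out, None
    out, rec = global_standardize(out)
    rec.species_mean_sl = {k: float(v) for k, v in sl_by_species.items()}
    return out, rec
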