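"""Leukocyte-anchored cell classification.

The core rule of the assay: every chip carries its own internal control — the
CD45+ leukocytes — and the NeuN positivity cut-off is their NeuN mean plus
``k`` standard deviations (k = 3 by default).  A nucleated (DAPI+) cell is
then called a CNC when it is CD45- and its NeuN intensity exceeds that
cut-off.  Because the cut-off is derived from measured leukocytes on the same
chip, any common multiplicative measurement factor cancels.

Classification is a total function with strict inequalities at every gate
boundary: a cell exactly on a threshold is never called positive
(conservative calling).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .errors import DegenerateDistributionError, ReferencePopulationError

logger = logging.getLogger(__name__)

LABEL_CNC = "cnc"
LABEL_LEUKOCYTE = "leukocyte"
LABEL_OTHER = "other"
LABEL_EXCLUDED = "excluded"


@dataclass
class GateModel:
    """The fitted classification rule for one sample (one chip).

    ``neun_cutoff`` equals ``leuko_neun_mean + k * leuko_neun_sd`` exactly
    (on the log1p scale when ``log_scale`` is set, back-transformed for
    classification).  The CD45 and DAPI thresholds separate leukocytes and
    nucleated cells respectively.
    """

    leuko_neun_mean: float
    leuko_neun_sd: float
    k: float
    neun_cutoff: float
    cd45_threshold: float
    dapi_threshold: float
    n_leukocytes_used: int
    log_scale: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GateModel":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class GatingSummary:
    """Class counts for one gated sample.

    ``n_total_counted`` counts all DAPI+ (non-excluded) cells, including the
    DAPI+/CD45-/NeuN-low 'other' class; ``cnc_fraction`` is None (undefined)
    when nothing was counted.
    """

    n_total_counted: int
    n_cnc: int
    n_leukocyte: int
    n_other: int
    n_excluded: int
    cnc_fraction: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def _values(cells, column: str) -> np.ndarray:
    if isinstance(cells, pd.DataFrame):
        return cells[column].to_numpy(float)
    return np.asarray(cells, dtype=float)


def fit_intensity_threshold(
    values,
    method: str = "auto",
    fixed_value: float | None = None,
    name: str = "intensity",
) -> float:
    """Two-class threshold for a marker whose negative class sits below a
    dominant bright mode (CD45 on a blood chip, 2-NBDG among mostly-live
    cells).

    ``method='auto'`` computes Otsu's split on log1p intensities and accepts
    it only when the two implied classes are credibly separated (inter-class
    mean gap exceeding twice the summed class SDs).  When the negative class
    is too rare for a variance-based split — the operating regime of a
    rare-cell assay — the threshold instead anchors on the dominant bright
    mode: its log-scale median minus 4 robust (MAD) SDs.  ``method='otsu'``
    is the unguarded split; ``method='fixed'`` returns ``fixed_value``.
    Degenerate distributions fall back to ``fixed_value`` with a logged
    warning, or raise when no fallback is configured.
    """
    if method == "fixed":
        if fixed_value is None:
            raise DegenerateDistributionError(
                f"fixed {name} threshold requested but no value configured"
            )
        return float(fixed_value)
    if method not in ("auto", "otsu"):
        raise ValueError(f"unknown threshold method {method!r}")

    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    logv = np.log1p(np.clip(vals, 0.0, None))

    def _fallback(reason: str) -> float:
        if fixed_value is not None:
            logger.warning(
                "automatic %s threshold failed (%s); falling back to fixed value %g",
                name, reason, fixed_value,
            )
            return float(fixed_value)
        raise DegenerateDistributionError(
            f"cannot derive automatic {name} threshold: {reason}"
        )

    if len(np.unique(logv)) < 2:
        return _fallback("fewer than 2 distinct values")

    t_log = float(threshold_otsu(logv))
    lo = logv[logv <= t_log]
    hi = logv[logv > t_log]
    separated = False
    if len(lo) and len(hi):
        s_lo = float(np.std(lo, ddof=1)) if len(lo) > 1 else 0.0
        s_hi = float(np.std(hi, ddof=1)) if len(hi) > 1 else 0.0
        separated = (float(np.mean(hi)) - float(np.mean(lo))) > 2.0 * (s_lo + s_hi)
    if separated or method == "otsu":
        if not (len(lo) and len(hi)):
            return _fallback("threshold does not split the data")
        return float(np.expm1(t_log))

    # Rare/absent negative class: anchor on the dominant bright mode.
    med = float(np.median(logv))
    mad_sd = 1.4826 * float(np.median(np.abs(logv - med)))
    if mad_sd <= 0:
        return _fallback("distribution is effectively a single value")
    t_log = med - 4.0 * mad_sd
    logger.info(
        "%s split not credibly bimodal; anchoring threshold on the dominant "
        "mode (log median %.3f - 4 x %.3f)", name, med, mad_sd,
    )
    return float(np.expm1(t_log))


def fit_cd45_threshold(
    cells,
    method: str = "auto",
    fixed_value: float | None = None,
) -> float:
    """CD45+/- threshold from the per-cell table (or a raw value array)."""
    return fit_intensity_threshold(
        _values(cells, "cd45"), method=method, fixed_value=fixed_value, name="CD45"
    )


def fit_neun_cutoff(
    cells: pd.DataFrame,
    cd45_threshold: float,
    dapi_threshold: float,
    k: float = 3.0,
    min_reference: int = 50,
    log_scale: bool = False,
) -> GateModel:
    """Fit the NeuN cut-off from the chip's own CD45+/DAPI+ leukocytes.

    The reference population is every cell with cd45 > cd45_threshold and
    dapi > dapi_threshold; the cut-off is its NeuN mean + k * sample SD
    (n-1 denominator).  Raises :class:`ReferencePopulationError` when the
    reference is smaller than ``min_reference``.
    """
    if k < 0:
        raise ValueError("k must be nonnegative")
    cd45 = cells["cd45"].to_numpy(float)
    dapi = cells["dapi"].to_numpy(float)
    ref = cells.loc[(cd45 > cd45_threshold) & (dapi > dapi_threshold), "neun"]
    ref = ref.to_numpy(float)
    ref = ref[np.isfinite(ref)]
    if len(ref) < min_reference:
        raise ReferencePopulationError(
            f"leukocyte reference population has {len(ref)} cells; "
            f"at least {min_reference} required"
        )
    data = np.log1p(ref) if log_scale else ref
    mean = float(np.mean(data))
    sd = float(np.std(data, ddof=1)) if len(data) > 1 else 0.0
    stat_cutoff = mean + k * sd
    cutoff = float(np.expm1(stat_cutoff)) if log_scale else stat_cutoff
    return GateModel(
        leuko_neun_mean=mean,
        leuko_neun_sd=sd,
        k=float(k),
        neun_cutoff=cutoff,
        cd45_threshold=float(cd45_threshold),
        dapi_threshold=float(dapi_threshold),
        n_leukocytes_used=int(len(ref)),
        log_scale=log_scale,
    )


def classify_cells(cells: pd.DataFrame, gate: GateModel) -> pd.DataFrame:
    """Label every cell: excluded / leukocyte / cnc / other.

    Order of gates: DAPI <= threshold excludes (debris, anucleate events);
    then CD45 > threshold calls a leukocyte regardless of NeuN; then
    NeuN > cutoff calls a CNC; the remainder (DAPI+/CD45-/NeuN-low) is
    'other'.  Missing intensities never pass a gate.
    """
    dapi = cells["dapi"].to_numpy(float)
    cd45 = cells["cd45"].to_numpy(float)
    neun = cells["neun"].to_numpy(float)

    with np.errstate(invalid="ignore"):
        dapi_pos = dapi > gate.dapi_threshold
        cd45_pos = cd45 > gate.cd45_threshold
        neun_pos = neun > gate.neun_cutoff

    labels = np.select(
        [~dapi_pos, cd45_pos, neun_pos],
        [LABEL_EXCLUDED, LABEL_LEUKOCYTE, LABEL_CNC],
        default=LABEL_OTHER,
    )
    out = cells.copy()
    out["label"] = labels
    return out


def summarize_gating(labeled: pd.DataFrame) -> GatingSummary:
    """Count classes; the CNC fraction is over all DAPI+ (counted) cells."""
    counts = labeled["label"].value_counts()
    n_cnc = int(counts.get(LABEL_CNC, 0))
    n_leuko = int(counts.get(LABEL_LEUKOCYTE, 0))
    n_other = int(counts.get(LABEL_OTHER, 0))
    n_excluded = int(counts.get(LABEL_EXCLUDED, 0))
    n_total = n_cnc + n_leuko + n_other
    fraction = (n_cnc / n_total) if n_total > 0 else None
    return GatingSummary(
        n_total_counted=n_total,
        n_cnc=n_cnc,
        n_leukocyte=n_leuko,
        n_other=n_other,
        n_excluded=n_excluded,
        cnc_fraction=fraction,
    )


def export_scatter(
    labeled: pd.DataFrame,
    gate: GateModel | None = None,
    scale: str = "linear",
) -> tuple[pd.DataFrame, dict]:
    """Per-cell (neun, cd45, label, block_id) table for NeuN-vs-CD45 plots.

    ``scale='log10'`` applies log10(1 + x) (pseudo-count convention, so zero
    intensity maps to zero).  Gate lines are returned as metadata on the same
    scale.
    """
    if scale not in ("linear", "log10"):
        raise ValueError(f"unknown scatter scale {scale!r}")
    table = labeled[["neun", "cd45", "label", "block_id"]].copy()
    meta: dict = {"scale": scale}
    if gate is not None:
        meta.update(
            neun_cutoff=gate.neun_cutoff,
            cd45_threshold=gate.cd45_threshold,
            dapi_threshold=gate.dapi_threshold,
            k=gate.k,
        )
    if scale == "log10":
        for col in ("neun", "cd45"):
            table[col] = np.log10(1.0 + np.clip(table[col].to_numpy(float), 0.0, None))
        if gate is not None:
            meta["neun_cutoff"] = float(np.log10(1.0 + gate.neun_cutoff))
            meta["cd45_threshold"] = float(np.log10(1.0 + gate.cd45_threshold))
    return table, meta


def dapi_threshold_from_noise(noise_sd: float, k: float = 3.0) -> float:
    """Default DAPI+ threshold on the measured (background-subtracted) scale:
    k noise SDs of the fixed-round image, i.e. anything resolvable above the
    background counts as nucleated."""
    return float(k * noise_sd)
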