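"""Regional deposition probabilities from raw PET-like voxel signals.

A reference region with no specific tracer binding (the cerebellum in
amyloid PET) anchors the calibration: bootstrap sub-samples of its voxel
values yield an empirical distribution of sub-sample maxima, fitted with a
Gumbel extreme-value law by maximum likelihood.  Each target voxel's signal
is then scored by the Gumbel CDF — the probability that the signal exceeds a
typical reference maximum — and voxel probabilities are aggregated per
region into a deposition-probability pattern.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EVDCalibration",
    "bootstrap_evd",
    "voxel_probability",
    "regional_pattern",
    "read_voxel_table",
    "voxel_table_from_nifti",
]


@dataclasses.dataclass
class EVDCalibration:
    """Fitted Gumbel law for reference-region sub-sample maxima."""

    location: float
    scale: float
    n_boot: int
    subsample_size: int
    rng_seed: int

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def bootstrap_evd(
    reference_values,
    n_boot: int = 40000,
    subsample_size: int = 100,
    rng_seed: int = 0,
) -> EVDCalibration:
    """Fit the extreme-value distribution of reference-region maxima.

    Draws ``n_boot`` sub-samples of ``subsample_size`` voxels with
    replacement, records each sub-sample maximum, and fits a Gumbel
    distribution to the maxima by maximum likelihood.  Deterministic given
    ``rng_seed``.
    """
    ref = np.asarray(reference_values, dtype=float).ravel()
    if ref.size == 0:
        raise ValueError("reference region is empty")
    if not np.all(np.isfinite(ref)):
        raise ValueError("non-finite reference values")
    if ref.std() == 0:
        raise ValueError("degenerate reference region (zero variance)")
    if subsample_size < 1:
        raise ValueError("subsample_size must be >= 1")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(rng_seed)
    idx = rng.integers(0, ref.size, size=(n_boot, subsample_size))
    maxima = ref[idx].max(axis=1)
    loc, scale = stats.gumbel_r.fit(maxima)
    return EVDCalibration(
        location=float(loc), scale=float(scale),
        n_boot=n_boot, subsample_size=subsample_size, rng_seed=rng_seed,
    )


def voxel_probability(value, calib: EVDCalibration):
    """Gumbel CDF of a voxel signal: P(signal >= typical reference maximum)."""
    out = stats.gumbel_r.cdf(np.asarray(value, dtype=float), calib.location, calib.scale)
    return out if np.ndim(out) else float(out)


def regional_pattern(
    voxels: pd.DataFrame,
    calib: EVDCalibration,
    region_order,
    aggregate: str = "mean",
) -> np.ndarray:
    """Deposition probability per region, following ``region_order``.

    ``voxels`` needs columns ``region_id`` and ``value``.  Each voxel is
    scored by :func:`voxel_probability` and aggregated within its region by
    the mean (default) or the maximum.
    """
    if aggregate not in ("mean", "max"):
        raise ValueError("aggregate must be 'mean' or 'max'")
    missing = set(region_order) - set(voxels["region_id"].unique())
    if missing:
        raise KeyError(f"regions missing from voxel table: {sorted(missing)}")
    probs = voxel_probability(voxels["value"].to_numpy(), calib)
    grouped = pd.Series(probs).groupby(voxels["region_id"].to_numpy()).agg(aggregate)
    return grouped.reindex(list(region_order)).to_numpy(dtype=float)


def read_voxel_table(path) -> pd.DataFrame:
    """Read a voxel table (TSV with columns region_id, value)."""
    df = pd.read_csv(path, sep="\t")
    if not {"region_id", "value"}.issubset(df.columns):
        raise ValueError("voxel table needs columns 'region_id' and 'value'")
    return df


def voxel_table_from_nifti(signal_path, label_path, label_names: dict) -> pd.DataFrame:
    """Build a voxel table from a signal image and an integer label volume.

    ``label_names`` maps integer label values to region names.  Requires
    nibabel (optional dependency).
    """
    import nibabel as nib

    sig = np.asarray(nib.load(str(signal_path)).dataobj, dtype=float).ravel()
    lab = np.asarray(nib.load(str(label_path)).dataobj).astype(int).ravel()
    if sig.shape != lab.shape:
        raise ValueError("signal and label volumes differ in size")
    rows = []
    for val, name in label_names.items():
        mask = lab == int(val)
        rows.append(pd.DataFrame({"region_id": name, "value": sig[mask]}))
    return pd.concat(rows, ignore_index=True)
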