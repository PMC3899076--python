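"""Radiometric calibration of mosaic digital numbers to σ⁰ backscatter.

The 50-m orthorectified L-band mosaic stores amplitudes as digital numbers
(DN). The normalized radar cross-section in decibels is

    σ⁰ = 10 · log10(DN²) + CF

with CF the absolute calibration factor, −83 dB for this product. DN = 0 is
mosaic fill and is treated as nodata, never as −∞ dB. Two derived bands are
computed from the calibrated channels: the band difference HH − HV (dB) and
the band ratio HH/HV taken on the dB values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import BackscatterStack, DualPolScene

__all__ = [
    "CalibrationConstant",
    "DEFAULT_CF",
    "calibrate_dn_to_db",
    "invert_db_to_dn",
    "derive_bands",
    "build_stack",
]


@dataclass(frozen=True)
class CalibrationConstant:
    """Absolute calibration factor (dB offset) of the mosaic product."""

    cf: float = -83.0

    def __post_init__(self):
        if not np.isfinite(self.cf):
            raise ValueError("calibration factor must be finite")


DEFAULT_CF = CalibrationConstant()


def _cf_value(cf) -> float:
    if isinstance(cf, CalibrationConstant):
        return cf.cf
    cf = float(cf)
    if not np.isfinite(cf):
        raise ValueError("calibration factor must be finite")
    return cf


def calibrate_dn_to_db(dn_grid, cf=DEFAULT_CF):
    """Convert digital numbers to σ⁰ in dB.

    Returns ``(db_grid, valid)``: σ⁰ = 10·log10(DN²) + CF where DN > 0;
    DN == 0 pixels are NaN in ``db_grid`` and False in ``valid``.

    Raises ``ValueError`` on any negative DN — amplitudes cannot be
    negative, so a negative value signals a corrupted input.
    """
    dn = np.asarray(dn_grid, dtype=float)
    if np.any(dn < 0):
        raise ValueError("negative digital number encountered; DN must be >= 0")
    cfv = _cf_value(cf)
    valid = dn > 0
    db = np.full(dn.shape, np.nan)
    db[valid] = 20.0 * np.log10(dn[valid]) + cfv
    if np.isscalar(dn_grid) or np.ndim(dn_grid) == 0:
        return float(db), bool(valid)
    return db, valid


def invert_db_to_dn(db_grid, cf=DEFAULT_CF):
    """Algebraic inverse of :func:`calibrate_dn_to_db`: DN = 10^((σ⁰−CF)/20).

    Returns continuous (unquantized) amplitudes; callers emulating the
    integer mosaic product round to the nearest positive integer themselves.
    """
    db = np.asarray(db_grid, dtype=float)
    dn = np.power(10.0, (db - _cf_value(cf)) / 20.0)
    if np.isscalar(db_grid) or np.ndim(db_grid) == 0:
        return float(dn)
    return dn


def derive_bands(hh_db, hv_db):
    """Band difference HH − HV (dB) and band ratio HH/HV on dB values.

    Returns ``(diff_db, ratio, ratio_valid)``. The ratio is undefined where
    HV is exactly 0 dB; such pixels are NaN in ``ratio`` and False in
    ``ratio_valid`` (σ⁰ = 0 dB lies outside every class box, so downstream
    classification loses nothing).
    """
    hh = np.asarray(hh_db, dtype=float)
    hv = np.asarray(hv_db, dtype=float)
    if hh.shape != hv.shape:
        raise ValueError(f"HH shape {hh.shape} != HV shape {hv.shape}")
    diff = hh - hv
    ratio_valid = hv != 0
    ratio = np.full(hh.shape, np.nan)
    ratio = np.divide(hh, hv, out=ratio, where=ratio_valid)
    if np.ndim(hh_db) == 0:
        return float(diff), float(ratio), bool(ratio_valid)
    return diff, ratio, ratio_valid


def build_stack(scene: DualPolScene, cf=DEFAULT_CF) -> BackscatterStack:
    """Calibrate a dual-pol scene and attach the derived bands.

    The scene's validity mask (already False at DN = 0 fill) propagates to
    every output band; the ratio band additionally flags HV = 0 dB pixels.
    """
    hh_db, hh_ok = calibrate_dn_to_db(scene.hh_dn, cf)
    hv_db, hv_ok = calibrate_dn_to_db(scene.hv_dn, cf)
    valid = scene.valid_mask & hh_ok & hv_ok
    diff, ratio, ratio_ok = derive_bands(
        np.where(valid, hh_db, np.nan), np.where(valid, hv_db, np.nan)
    )
    return BackscatterStack(
        hh_db=np.where(valid, hh_db, np.nan),
        hv_db=np.where(valid, hv_db, np.nan),
        diff_db=diff,
        ratio=ratio,
        valid_mask=valid,
        transform=scene.transform,
        ratio_valid=valid & ratio_ok,
    )
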