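"""Brute-force voxel oracle for the layered-slab melt bookkeeping.

Replays a recorded melt history (per-layer lateral erosion plus surface and
basal trims) on an explicit grid of 1 m³ voxels, computing every voxel's
remaining ice volume and iron by exact box clipping against the remaining
region and the high-Fe frame of each layer.  Shares no geometry arithmetic
with the production slab model beyond the initial state description.
"""

from __future__ import annotations

import numpy as np

from bergfert.melt_sim import IcebergState, StepRecord


def _overlap(lo_a: np.ndarray, hi_a: np.ndarray, lo_b: float, hi_b: float) -> np.ndarray:
    return np.clip(np.minimum(hi_a, hi_b) - np.maximum(lo_a, lo_b), 0.0, None)


def voxel_replay(state0: IcebergState, history: list[StepRecord]):
    """Daily (volume, Fe) series from voxel integration of the melt history.

    ``state0`` must be the state as constructed by ``assign_fe`` (before any
    stepping); ``history`` the per-day records of a production run.
    Returns arrays of length ``len(history) + 1`` including the initial state.
    """
    l0, w0 = state0.length0, state0.width0
    lo0, hi0 = state0.lo.copy(), state0.hi.copy()
    h, c_int, c_high = state0.h, state0.c_int, state0.c_high

    # voxel edges (1 m cells, fractional last cell per axis)
    def edges(extent: float) -> np.ndarray:
        e = np.arange(0.0, np.floor(extent) + 1.0)
        if extent - e[-1] > 1e-12:
            e = np.append(e, extent)
        return e

    xe, ye, ze = edges(l0), edges(w0), edges(float(hi0[-1]))
    xlo, xhi = xe[:-1], xe[1:]
    ylo, yhi = ye[:-1], ye[1:]
    zlo, zhi = ze[:-1], ze[1:]

    cum_e = np.zeros_like(state0.e)
    z_top, z_bot = float(lo0[0]), float(hi0[-1])
    volumes, irons = [], []

    def measure() -> tuple[float, float]:
        total_vol = 0.0
        total_fe = 0.0
        for j in range(len(lo0)):
            a, b = max(lo0[j], z_top), min(hi0[j], z_bot)
            if b <= a:
                continue
            zov = _overlap(zlo, zhi, a, b)  # per z-voxel
            e = cum_e[j]
            xov = _overlap(xlo, xhi, e, l0 - e)
            yov = _overlap(ylo, yhi, e, w0 - e)
            if xov.sum() <= 0 or yov.sum() <= 0:
                continue
            # interior (below the high-Fe frame) box of this layer
            hh = max(e, h[j])
            xov_in = _overlap(xlo, xhi, hh, l0 - hh)
            yov_in = _overlap(ylo, yhi, hh, w0 - hh)
            plan = np.outer(xov, yov)  # per-voxel plan areas
            plan_in = np.outer(xov_in, yov_in)
            vol = plan.sum() * zov.sum()
            vol_in = plan_in.sum() * zov.sum()
            total_vol += vol
            total_fe += 1000.0 * (c_high * (vol - vol_in) + c_int[j] * vol_in)
        return total_vol, total_fe

    v, f = measure()
    volumes.append(v)
    irons.append(f)
    for rec in history:
        cum_e = cum_e + rec.lateral_erosion
        z_top += rec.surface_lowering
        z_bot -= rec.basal_rise
        v, f = measure()
        volumes.append(v)
        irons.append(f)
    return np.array(volumes), np.array(irons)
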