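"""Shared driver for exercising the step kernel on toy systems."""

import numpy as np

from agropast import _kernel


def kernel_steps(ls, herd, params, n_steps=1, step_offset=0, growing=False,
                 crop_step=None, wood_step=None, moves_per_day=0,
                 move_dirs=None, plough_window_steps=0):
    """Drive the shared step kernel (pure-Python path) on a toy system."""
    side = ls.side
    n_p = side * side
    boundary_idx = np.flatnonzero(ls.boundary_crop_mask().ravel())
    if move_dirs is None:
        move_dirs = np.zeros((n_steps, herd.n_slots), dtype=np.int8)
    raid_u = np.ones((max(n_steps, 1), boundary_idx.size))
    crop_step = np.zeros(n_p) if crop_step is None else crop_step
    wood_step = np.zeros(n_p) if wood_step is None else wood_step
    has_growth = bool(crop_step.any() or wood_step.any())
    acc = np.zeros(_kernel.N_ACC)
    wood_total = float(ls.biomass.ravel()[ls.kind.ravel() == 0].sum())
    acc[_kernel.A_WOOD_MIN] = wood_total
    wt = _kernel.simulate_steps_py(
        n_steps, step_offset, side, 3, growing, has_growth,
        ls.kind.ravel(), ls.biomass.ravel(), ls.residue.ravel(),
        ls.fence_intact.ravel(), crop_step, wood_step, boundary_idx,
        herd.n_slots, herd.r, herd.c, herd.mass, herd.alive, herd.adult,
        herd.transported, herd.fed, herd.working,
        move_dirs, raid_u,
        moves_per_day, params.search_radius, plough_window_steps,
        params.eta_browse, params.eta_crop, params.eta_cow,
        params.eta_c, params.eta_a,
        params.e_maint, params.e_work, params.intake_max,
        params.forage_access_frac,
        params.m_min, params.juvenile_min_frac * params.m_birth,
        params.m_max, params.m_mature,
        params.fence_break_prob, params.feed_price,
        params.woodland_carrying_capacity,
        acc, herd.pending_intake, np.zeros(n_p), np.zeros(n_p),
        np.zeros(n_p, dtype=np.int64), np.zeros(n_p),
        np.zeros(n_p, dtype=np.int64), np.zeros(side, dtype=np.int64),
        wood_total)
    return acc, wt
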