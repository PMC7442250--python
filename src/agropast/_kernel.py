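"""Per-step dynamics kernel shared by the jitted and pure-Python engines.

One model step is 8 hours (3 per day).  Within a step the kernel applies,
in order: vegetation growth deposition, crop raids through broken fences,
and the cow loop (movement, grazing, supplemental feed, energy balance,
mass update, death, maturation).  All stochastic inputs (random-walk
directions, raid triggers) are pre-drawn by the orchestrator and passed in
as arrays, so running the kernel through numba or as plain Python gives
bit-identical trajectories.

Energy bookkeeping per cow per step, with ``E`` the net energy
(intake minus maintenance minus work, MJ):

* ``E >= 0``: mass gain ``dm = eta_a * E / eta_cow``, capped at ``m_max``
  (the energy that would overshoot the cap is discarded);
* ``E < 0``: mass loss ``dm = E / (eta_c * eta_cow)``;
* death when mass drops below the stage's viability threshold
  (``m_min`` for adults, ``m_min_juv`` for juveniles).

Maintenance, maximum intake and the feed ration all scale allometrically
with ``(mass / m_mature) ** 0.75``.  Grazing follows a linear functional
response: a visit gathers at most ``forage_frac`` of the patch's standing
forage, and a cow near peak condition only eats what it can use
(maintenance, work and the energy room up to ``m_max``).

Every biomass and energy flow is accumulated into the ``acc`` ledger so the
orchestrator can verify conservation at the end of each year.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit as _njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(fn):
            return fn
        return deco

# ---------------------------------------------------------------------------
# ledger accumulator indices
A_GRAZE_WOOD = 0     # woodland browse eaten, kg
A_GRAZE_RES = 1      # crop residue eaten, kg
A_RAID = 2           # standing crop eaten through broken fences, kg
A_FEED_MJ = 3        # supplemental feed energy delivered, MJ
A_MAINT = 4          # maintenance energy paid, MJ
A_WORK = 5           # ploughing work energy paid, MJ
A_ANAB = 6           # energy converted to tissue (incl. conversion loss), MJ
A_CATAB = 7          # energy supplied by tissue catabolism, MJ
A_DISCARD = 8        # surplus energy discarded at the mass cap, MJ
A_DM = 9             # net cow mass change, kg
A_DIED_MASS = 10     # mass of cows at death, kg
A_WOOD_GROWTH = 11   # woodland biomass deposited, kg
A_CROP_GROWTH = 12   # standing crop biomass deposited, kg
A_SPEND = 13         # subsidy spend, currency
A_FEED_KG = 14       # supplemental feed mass, kg
A_WOOD_MIN = 15      # running minimum of total woodland biomass, kg
N_ACC = 16

KIND_WOODLAND = 0
KIND_CROP = 1


def _window_best(values, side, radius, rv, ra, fv, fr, qidx):
    """Two-pass sliding-window argmax over a (side x side) grid.

    After the call, for the window centred on patch ``(r, c)``:
    ``fv[r*side+c]`` is the maximum of ``values`` within Chebyshev radius
    ``radius`` and the maximizing patch is ``(fr[r*side+c],
    ra[fr[r*side+c]*side + c])``.  Ties resolve to the smallest row, then
    the smallest column (monotonic-deque passes keep the earliest index).
    """
    for r in range(side):
        base = r * side
        head = 0
        tail = 0
        j_add = 0
        for c in range(side):
            hi = c + radius
            if hi > side - 1:
                hi = side - 1
            while j_add <= hi:
                v = values[base + j_add]
                while tail > head and values[base + qidx[tail - 1]] < v:
                    tail -= 1
                qidx[tail] = j_add
                tail += 1
                j_add += 1
            lo = c - radius
            while qidx[head] < lo:
                head += 1
            rv[base + c] = values[base + qidx[head]]
            ra[base + c] = qidx[head]
    for c in range(side):
        head = 0
        tail = 0
        j_add = 0
        for r in range(side):
            hi = r + radius
            if hi > side - 1:
                hi = side - 1
            while j_add <= hi:
                v = rv[j_add * side + c]
                while tail > head and rv[qidx[tail - 1] * side + c] < v:
                    tail -= 1
                qidx[tail] = j_add
                tail += 1
                j_add += 1
            lo = r - radius
            while qidx[head] < lo:
                head += 1
            rbest = qidx[head]
            fv[r * side + c] = rv[rbest * side + c]
            fr[r * side + c] = rbest


def simulate_steps(
    n_steps, step_offset, side, steps_per_day, growing, has_growth,
    kind, biomass, residue, fence_ok,
    crop_step, wood_step,
    boundary_idx,
    n_slots, cow_r, cow_c, cow_mass, cow_alive, cow_adult,
    cow_transported, cow_fed, cow_working,
    move_dirs, raid_u,
    moves_per_day, search_radius, plough_window_steps,
    eta_browse, eta_crop, eta_cow, eta_c, eta_a,
    e_maint, e_work, intake_max, forage_frac, m_min, m_min_juv, m_max, m_mature,
    fence_break_prob, feed_price, wood_k,
    acc, raid_extra, gval, win_rv, win_ra, win_fv, win_fr, qidx,
    wood_total,
):
    """Advance the system ``n_steps`` 8-hour steps.  Returns updated wood_total."""
    n_patches = side * side
    n_boundary = boundary_idx.shape[0]
    for t in range(n_steps):
        t_abs = step_offset + t

        # -- vegetation growth deposition ---------------------------------
        if has_growth:
            for p in range(n_patches):
                ws = wood_step[p]
                if ws > 0.0:
                    room = wood_k - biomass[p]
                    inc = ws if ws < room else room
                    if inc > 0.0:
                        biomass[p] += inc
                        acc[A_WOOD_GROWTH] += inc
                        wood_total += inc
                else:
                    cs = crop_step[p]
                    if cs > 0.0:
                        biomass[p] += cs
                        acc[A_CROP_GROWTH] += cs

        # -- crop raids through broken fences -----------------------------
        for i in range(n_slots):
            raid_extra[i] = 0.0
        if growing:
            for b in range(n_boundary):
                p = boundary_idx[b]
                if fence_ok[p]:
                    continue
                if biomass[p] <= 0.0:
                    continue
                if raid_u[t, b] >= fence_break_prob:
                    continue
                pr = p // side
                pc = p % side
                raider = -1
                for i in range(n_slots):
                    if cow_alive[i] == 0 or cow_transported[i] == 1:
                        continue
                    dr = cow_r[i] - pr
                    if dr < 0:
                        dr = -dr
                    dc = cow_c[i] - pc
                    if dc < 0:
                        dc = -dc
                    if dr + dc <= 1:
                        raider = i
                        break
                if raider >= 0:
                    s = (cow_mass[raider] / m_mature) ** 0.75
                    eat = intake_max * s - raid_extra[raider]
                    if eat > biomass[p]:
                        eat = biomass[p]
                    if eat > 0.0:
                        biomass[p] -= eat
                        raid_extra[raider] += eat
                        acc[A_RAID] += eat

        # -- farmer-directed move targets ----------------------------------
        directed = (t_abs % steps_per_day) < moves_per_day
        if directed:
            for p in range(n_patches):
                if kind[p] == KIND_WOODLAND:
                    gval[p] = biomass[p]
                else:
                    gval[p] = residue[p]
            _window_best(gval, side, search_radius,
                         win_rv, win_ra, win_fv, win_fr, qidx)

        # -- cow loop ------------------------------------------------------
        for i in range(n_slots):
            if cow_alive[i] == 0 or cow_transported[i] == 1:
                continue
            r = cow_r[i]
            c = cow_c[i]
            if directed:
                p0 = r * side + c
                if win_fv[p0] > 0.0:
                    br = win_fr[p0]
                    bc = win_ra[br * side + c]
                    r = br
                    c = bc
            else:
                d = move_dirs[t, i]
                nr = r
                nc = c
                if d == 0:
                    nr = r - 1
                elif d == 1:
                    nr = r + 1
                elif d == 2:
                    nc = c - 1
                else:
                    nc = c + 1
                if 0 <= nr < side and 0 <= nc < side:
                    np_idx = nr * side + nc
                    blocked = (growing and kind[np_idx] == KIND_CROP
                               and fence_ok[np_idx])
                    if not blocked:
                        # forage-seeking: never leave food for a bare patch
                        g_here = (biomass[r * side + c]
                                  if kind[r * side + c] == KIND_WOODLAND
                                  else residue[r * side + c])
                        g_there = (biomass[np_idx]
                                   if kind[np_idx] == KIND_WOODLAND
                                   else residue[np_idx])
                        if g_there > 0.0 or g_here <= 0.0:
                            r = nr
                            c = nc
            cow_r[i] = r
            cow_c[i] = c
            p = r * side + c

            s = (cow_mass[i] / m_mature) ** 0.75
            maint = e_maint * s
            acc[A_MAINT] += maint
            work = 0.0
            if cow_working[i] == 1 and t_abs < plough_window_steps:
                work = e_work
                acc[A_WORK] += work

            intake_mj = raid_extra[i] * eta_crop
            # satiety: graze only what maintenance, work and the remaining
            # growth room up to m_max can absorb
            e_room = (maint + work
                      + (m_max - cow_mass[i]) * eta_cow / eta_a - intake_mj)
            cap_kg = intake_max * s - raid_extra[i]
            if cap_kg < 0.0:
                cap_kg = 0.0
            if kind[p] == KIND_WOODLAND:
                eat = cap_kg
                acc_avail = forage_frac * biomass[p]
                if eat > acc_avail:
                    eat = acc_avail
                sat = e_room / eta_browse if e_room > 0.0 else 0.0
                if eat > sat:
                    eat = sat
                if eat > 0.0:
                    biomass[p] -= eat
                    wood_total -= eat
                    acc[A_GRAZE_WOOD] += eat
                    intake_mj += eat * eta_browse
            else:
                eat = cap_kg
                acc_avail = forage_frac * residue[p]
                if eat > acc_avail:
                    eat = acc_avail
                sat = e_room / eta_crop if e_room > 0.0 else 0.0
                if eat > sat:
                    eat = sat
                if eat > 0.0:
                    residue[p] -= eat
                    acc[A_GRAZE_RES] += eat
                    intake_mj += eat * eta_crop
            if cow_fed[i] == 1:
                feed_mj = e_maint * s
                intake_mj += feed_mj
                acc[A_FEED_MJ] += feed_mj
                feed_kg = feed_mj / eta_crop
                acc[A_FEED_KG] += feed_kg
                acc[A_SPEND] += feed_kg * feed_price
            energy = intake_mj - maint - work
            if energy >= 0.0:
                dm = eta_a * energy / eta_cow
                new_m = cow_mass[i] + dm
                if new_m > m_max:
                    used_dm = m_max - cow_mass[i]
                    used_mj = used_dm * eta_cow / eta_a
                    acc[A_ANAB] += used_mj
                    acc[A_DISCARD] += energy - used_mj
                    dm = used_dm
                    new_m = m_max
                else:
                    acc[A_ANAB] += energy
                cow_mass[i] = new_m
                acc[A_DM] += dm
            else:
                dm = energy / (eta_c * eta_cow)
                acc[A_CATAB] += -energy
                cow_mass[i] += dm
                acc[A_DM] += dm
            if cow_adult[i] == 0 and cow_mass[i] >= m_mature:
                cow_adult[i] = 1
            thresh = m_min if cow_adult[i] == 1 else m_min_juv
            if cow_mass[i] < thresh:
                cow_alive[i] = 0
                acc[A_DIED_MASS] += cow_mass[i]

        if wood_total < acc[A_WOOD_MIN]:
            acc[A_WOOD_MIN] = wood_total
    return wood_total


# plain-Python references (always available)
window_best_py = _window_best
simulate_steps_py = simulate_steps

if HAVE_NUMBA:
    _window_best = _njit(cache=False)(_window_best)
    simulate_steps_jit = _njit(cache=False)(simulate_steps)
else:  # pragma: no cover
    simulate_steps_jit = simulate_steps
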