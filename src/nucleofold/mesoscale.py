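"""Coarse-grained chromatin fiber model and Metropolis Monte Carlo sampler.

Representation: rigid nucleosome cores (position + orthonormal frame)
carrying fixed surface pseudo-charges, optional rigid linker-histone
beads and flexible histone-tail chains; linker DNA as beads at 3.0 nm
spacing (8.8 bp/bead).  Energies (kBT units): harmonic stretch, discrete
worm-like-chain bending (including entry/exit joints at the cores),
screened Coulomb electrostatics with an optional DNA-DNA screening
override (implicit Mg), purely repulsive truncated-shifted 12-6 excluded
volume with a finite core-core cap, and a 3 nm spring for zero-length
linkers.  Zero-linker templates therefore always sample finite energies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .constants import BEAD_SPACING_NM, BP_PER_BEAD

logger = logging.getLogger("nucleofold")

# bead type codes
T_LINKER, T_CORE, T_TAIL, T_LH = 0, 1, 2, 3
KIND_NAMES = {T_LINKER: "linker", T_CORE: "core", T_TAIL: "tail", T_LH: "lh"}


def discretize_linker(bp: float) -> int:
    """Bead count for a linker: max(0, round(bp / 8.8235))."""
    return max(0, int(round(bp / BP_PER_BEAD)))


@dataclass(frozen=True)
class FiberTemplate:
    """Simulator topology: per-linker bead counts and LH occupancy."""

    n_cores: int
    linker_beads: tuple[int, ...]
    lh_occupancy: tuple[float, ...]
    linker_bp: tuple[float, ...] = ()

    def __post_init__(self):
        if self.n_cores < 2:
            raise ValueError("need at least 2 cores")
        if len(self.linker_beads) != self.n_cores - 1:
            raise ValueError("need n_cores - 1 linker bead counts")
        if any(b < 0 for b in self.linker_beads):
            raise ValueError("bead counts must be >= 0")

    @property
    def zero_linkers(self) -> tuple[int, ...]:
        return tuple(i for i, b in enumerate(self.linker_beads) if b == 0)


@dataclass
class EnergyParams:
    """Model parameters; all energies in kBT, lengths in nm, charges in e.

    The charge set is phenomenological (post counterion condensation) and
    is treated as a calibration input.
    """

    temperature_K: float = 293.0
    bead_spacing_nm: float = BEAD_SPACING_NM
    stretch_k: float = 100.0  # kBT / nm^2
    persistence_nm: float = 50.0
    zero_linker_nm: float = 3.0
    zero_linker_k: float = 100.0
    debye_nm: float = 0.785  # monovalent screening length
    debye_dd_nm: float | None = None  # DNA-DNA override (implicit Mg)
    bjerrum_nm: float = 0.7
    q_linker: float = -15.0
    q_core_total: float = -100.0
    n_core_charges: int = 12
    q_tail: float = 1.2
    q_lh: float = 8.0
    sigma_linker: float = 1.8
    sigma_core: float = 2.0
    sigma_tail: float = 1.0
    sigma_lh: float = 1.2
    ev_eps: float = 1.0
    #: per-pair cap on the repulsive 12-6 term (soft excluded volume); this
    #: keeps overlapping-nucleosome configurations at finite energy
    ev_cap_kbt: float = 20.0
    #: distance floor for the screened Coulomb (prevents collapse once the
    #: excluded volume is capped)
    elec_min_nm: float = 0.5
    tails: bool = True
    tail_bond_nm: float = 1.5
    tail_bond_k: float = 60.0
    # entry/exit half-angle of the linker directions, deg
    stem_angle_deg: float = 12.0
    open_angle_deg: float = 50.0
    #: stiffness multiplier for the entry/exit joints (LH clamping of the
    #: linker directions at the core)
    anchor_bend_mult: float = 6.0
    charges_on: bool = True

    @property
    def bend_modulus(self) -> float:
        """Discrete WLC modulus per joint, kBT: Lp / l0."""
        return self.persistence_nm / self.bead_spacing_nm if self.bead_spacing_nm else 0.0


def set_conditions(
    params: EnergyParams,
    nacl_mm: float,
    mg: bool = False,
    literal_kappa: bool = False,
) -> EnergyParams:
    """Return params for a salt condition.

    Monovalent Debye screening length at 293 K: 0.304 / sqrt(c[M]) nm.
    Implicit-Mg mode additionally overrides the DNA-DNA screening length
    and reduces the DNA persistence length from 50 to 30 nm.  The override
    defaults to 1/2.5 = 0.4 nm (reading the quoted kappa as an inverse
    length); ``literal_kappa`` selects the literal 2.5 nm reading for
    sensitivity analysis.
    """
    if nacl_mm <= 0:
        raise ValueError("NaCl concentration must be > 0")
    lam = 0.304 / np.sqrt(nacl_mm / 1000.0)
    if mg:
        lam_dd = 2.5 if literal_kappa else 1.0 / 2.5
        logger.info(
            "implicit-Mg mode: DNA-DNA screening length %.3f nm, Lp 30 nm", lam_dd
        )
        return replace(params, debye_nm=lam, debye_dd_nm=lam_dd, persistence_nm=30.0)
    return replace(params, debye_nm=lam, debye_dd_nm=None, persistence_nm=50.0)


# ---------------------------------------------------------------------------
# core body-frame geometry (nm).  x: toward the dyad/linker side (the
# linkers leave in -x), z: superhelical axis.

_PSEUDO_BODY = np.array(
    [
        [4.0 * np.cos(a), 4.0 * np.sin(a), z]
        for z in (-1.8, 1.8)
        for a in np.deg2rad(np.arange(6) * 60.0 + (15.0 if z > 0 else 45.0))
    ]
)
_LH_BODY = np.array(
    [[-4.5 - 1.5 * k, 0.0, 0.0] for k in range(5)]
)  # rail along the dyad axis between the entry/exit linkers
_TAIL_ATTACH_BODY = np.array(
    [
        [5.0 * np.cos(a), 5.0 * np.sin(a), 2.2 * (1 if i % 2 else -1)]
        for i, a in enumerate(np.deg2rad(np.arange(8) * 45.0 + 22.5))
    ]
)
_ANCHOR_IN_BODY = np.array([-3.5, 0.9, 0.6])
_ANCHOR_OUT_BODY = np.array([-3.5, -0.9, -0.6])


def _anchor_dirs(angle_deg: float, stem: bool) -> tuple[np.ndarray, np.ndarray]:
    """Entry/exit linker directions in the core frame.

    With a stem (LH-clamped), the exit runs antiparallel to the entry so the
    two linkers form a narrow parallel stem.  Without a stem the linkers fan
    out on the dyad side (the chain turns by ~180 - 2*angle instead of
    reversing), as for chromatosomes lacking the LH clamp.
    """
    phi = np.deg2rad(angle_deg)
    d_in = np.array([np.cos(phi), np.sin(phi), 0.0])  # travel direction into core
    if stem:
        d_out = np.array([-np.cos(phi), -np.sin(phi), 0.0])
    else:
        d_out = np.array([-np.cos(phi), np.sin(phi), 0.0])
    return d_in, d_out


@dataclass
class System:
    """Flattened interacting-bead representation of one fiber."""

    template: FiberTemplate
    params: EnergyParams
    # static per-bead arrays
    q: np.ndarray
    typ: np.ndarray
    owner: np.ndarray
    linker_id: np.ndarray
    slot: np.ndarray
    excl1: np.ndarray
    excl2: np.ndarray
    # topology
    linker_start: np.ndarray
    linker_len: np.ndarray
    core_block_start: np.ndarray
    core_block_end: np.ndarray
    body_pos: np.ndarray  # per core-owned bead, body-frame position
    tail_chain_core: np.ndarray
    tail_chain_attach: np.ndarray  # (n_chains, 3) body frame
    tail_chain_start: np.ndarray  # first bead index of each 3-bead chain
    anchor_in_dir: np.ndarray  # (n_cores, 3) body frame
    anchor_out_dir: np.ndarray
    anchor_g: np.ndarray  # (n_cores,) bend modulus at the entry/exit joints
    mobile: np.ndarray  # indices of linker+tail beads

    @property
    def n_beads(self) -> int:
        return len(self.q)

    def bead_kinds(self) -> list[str]:
        return [KIND_NAMES[int(t)] for t in self.typ]

    def sigma_matrix(self) -> np.ndarray:
        p = self.params
        s = np.array([p.sigma_linker, p.sigma_core, p.sigma_tail, p.sigma_lh])
        return (s[:, None] + s[None, :]) / 2.0


@dataclass
class State:
    core_pos: np.ndarray  # (n_cores, 3)
    core_rot: np.ndarray  # (n_cores, 3, 3)
    bead_pos: np.ndarray  # (n_beads, 3)

    def copy(self) -> "State":
        return State(self.core_pos.copy(), self.core_rot.copy(), self.bead_pos.copy())


def build_system(template: FiberTemplate, params: EnergyParams) -> System:
    nc = template.n_cores
    q, typ, owner, linker_id, slot, excl1, excl2, body = [], [], [], [], [], [], [], []
    linker_start = np.zeros(nc - 1, dtype=np.int64)
    linker_len = np.asarray(template.linker_beads, dtype=np.int64)
    idx = 0
    for li, nb in enumerate(template.linker_beads):
        linker_start[li] = idx
        for s in range(nb):
            q.append(params.q_linker)
            typ.append(T_LINKER)
            owner.append(-1)
            linker_id.append(li)
            slot.append(s)
            excl1.append(li if s == 0 else -1)
            excl2.append(li + 1 if s == nb - 1 else -1)
            body.append((0.0, 0.0, 0.0))
            idx += 1
    core_block_start = np.zeros(nc, dtype=np.int64)
    core_block_end = np.zeros(nc, dtype=np.int64)
    tail_chain_core, tail_chain_attach, tail_chain_start = [], [], []
    anchor_in_dir = np.zeros((nc, 3))
    anchor_out_dir = np.zeros((nc, 3))
    anchor_g = np.zeros(nc)
    g = params.bend_modulus
    for c in range(nc):
        occ = template.lh_occupancy[c]
        # the narrow LH-clamped stem geometry needs LH *and* linkers long
        # enough on every existing flank (>= 3 beads, i.e. > 26 bp)
        flanks = [li for li in (c - 1, c) if 0 <= li < nc - 1]
        stem_capable = occ > 0 and all(
            template.linker_beads[li] >= 3 for li in flanks
        )
        angle = params.stem_angle_deg if stem_capable else params.open_angle_deg
        anchor_g[c] = g * (params.anchor_bend_mult if stem_capable else 1.0)
        anchor_in_dir[c], anchor_out_dir[c] = _anchor_dirs(angle, stem_capable)
        core_block_start[c] = idx
        qc = params.q_core_total / params.n_core_charges
        for b in _PSEUDO_BODY[: params.n_core_charges]:
            q.append(qc)
            typ.append(T_CORE)
            owner.append(c)
            linker_id.append(-1)
            slot.append(-1)
            excl1.append(c)
            excl2.append(-1)
            body.append(tuple(b))
            idx += 1
        if occ > 0:
            for b in _LH_BODY:
                q.append(params.q_lh * occ)
                typ.append(T_LH)
                owner.append(c)
                linker_id.append(-1)
                slot.append(-1)
                excl1.append(c)
                excl2.append(-1)
                body.append(tuple(b))
                idx += 1
        if params.tails:
            for t, attach in enumerate(_TAIL_ATTACH_BODY):
                tail_chain_core.append(c)
                tail_chain_attach.append(attach)
                tail_chain_start.append(idx)
                u = attach / np.linalg.norm(attach)
                for k in range(3):
                    q.append(params.q_tail)
                    typ.append(T_TAIL)
                    owner.append(c)
                    linker_id.append(-1)
                    slot.append(k)
                    excl1.append(c)
                    excl2.append(-1)
                    body.append(tuple(attach + params.tail_bond_nm * (k + 1) * u))
                    idx += 1
        core_block_end[c] = idx
    qa = np.asarray(q)
    if not params.charges_on:
        qa = np.zeros_like(qa)
    mobile = np.where(
        (np.asarray(typ) == T_LINKER) | (np.asarray(typ) == T_TAIL)
    )[0].astype(np.int64)
    return System(
        template=template,
        params=params,
        q=qa,
        typ=np.asarray(typ, dtype=np.int64),
        owner=np.asarray(owner, dtype=np.int64),
        linker_id=np.asarray(linker_id, dtype=np.int64),
        slot=np.asarray(slot, dtype=np.int64),
        excl1=np.asarray(excl1, dtype=np.int64),
        excl2=np.asarray(excl2, dtype=np.int64),
        linker_start=linker_start,
        linker_len=linker_len,
        core_block_start=core_block_start,
        core_block_end=core_block_end,
        body_pos=np.asarray(body),
        tail_chain_core=np.asarray(tail_chain_core, dtype=np.int64),
        tail_chain_attach=(
            np.asarray(tail_chain_attach) if tail_chain_attach else np.zeros((0, 3))
        ),
        tail_chain_start=np.asarray(tail_chain_start, dtype=np.int64),
        anchor_in_dir=anchor_in_dir,
        anchor_out_dir=anchor_out_dir,
        anchor_g=anchor_g,
        mobile=mobile,
    )


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a to unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if c < -1 + 1e-12:
        # pick any perpendicular axis for the 180 deg case
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-9:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return _axis_angle(axis, np.pi)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def initial_configuration(system: System, mode: str = "open") -> State:
    """Deterministic starting configuration.

    mode="open" (default): cores along a straight axis at their natural
    linker contour spacing, alternating dyad orientation; linker beads
    interpolate between the anchors.  Compaction is then driven entirely
    by the energetics during sampling.

    mode="native": chain-grown two-start geometry with straight linkers
    and the helical twist register per linker (the downstream frame is
    pre-rotated about the linker axis by 360 deg * (L mod 10.5) / 10.5).
    """
    if mode == "open":
        return _open_configuration(system)
    if mode != "native":
        raise ValueError("mode must be 'open' or 'native'")
    return _native_configuration(system)


def _open_configuration(system: System) -> State:
    tpl = system.template
    nc = tpl.n_cores
    core_pos = np.zeros((nc, 3))
    core_rot = np.zeros((nc, 3, 3))
    bead_pos = np.zeros((system.n_beads, 3))
    # alternating dyad orientation: linker side (-x body) faces +/- Y
    r_even = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]).T
    flip = _axis_angle(np.array([0.0, 0.0, 1.0]), np.pi)
    x = 0.0
    for c in range(nc):
        core_pos[c] = (x, 0.0, 0.0)
        core_rot[c] = r_even if c % 2 == 0 else flip @ r_even
        if c < nc - 1:
            nb = int(system.linker_len[c])
            x += max(3.0 * (nb + 1) + 6.0, 9.5)
    for li in range(nc - 1):
        nb = int(system.linker_len[li])
        if nb == 0:
            continue
        a_out = core_pos[li] + core_rot[li] @ _ANCHOR_OUT_BODY
        a_in = core_pos[li + 1] + core_rot[li + 1] @ _ANCHOR_IN_BODY
        for sl in range(nb):
            t = (sl + 1) / (nb + 1)
            bead_pos[system.linker_start[li] + sl] = a_out + t * (a_in - a_out)
    state = State(core_pos=core_pos, core_rot=core_rot, bead_pos=bead_pos)
    sync_rigid_beads(system, state)
    return state


def _native_configuration(system: System) -> State:
    from .constants import HELICAL_REPEAT_BP

    tpl = system.template
    nc = tpl.n_cores
    l0 = system.params.bead_spacing_nm
    core_pos = np.zeros((nc, 3))
    core_rot = np.zeros((nc, 3, 3))
    core_rot[0] = np.eye(3)
    bead_pos = np.zeros((system.n_beads, 3))
    g_mod = system.params.bend_modulus
    for li in range(nc - 1):
        c = li
        R = core_rot[c]
        p = core_pos[c]
        a_out = p + R @ _ANCHOR_OUT_BODY
        d_out = R @ system.anchor_out_dir[c]
        nb = int(system.linker_len[li])
        # a junction is 'floppy' when either flanking core lacks the
        # LH-clamped stem geometry; its linker is laid out curving away
        # from the existing mass (open necklace), not into a zigzag turn
        floppy = g_mod > 0 and (
            system.anchor_g[c] <= 1.5 * g_mod
            or system.anchor_g[c + 1] <= 1.5 * g_mod
        )
        centroid = core_pos[: c + 1].mean(axis=0)
        away = a_out - centroid
        away = (
            away / np.linalg.norm(away)
            if np.linalg.norm(away) > 1e-9
            else np.array([1.0, 0.0, 0.0])
        )
        node = a_out
        bond = d_out
        for s in range(nb):
            if floppy and nb >= 2:
                f = (s + 1) / (nb + 1)
                bond = (1 - f) * d_out + f * away
                bond = bond / np.linalg.norm(bond)
            node = node + l0 * bond
            bead_pos[system.linker_start[li] + s] = node
        a_in_next = node + (
            l0 if nb > 0 else system.params.zero_linker_nm
        ) * bond
        bp_val = tpl.linker_bp[li] if tpl.linker_bp else nb * BP_PER_BEAD
        twist = 2.0 * np.pi * (max(bp_val, 0.0) % HELICAL_REPEAT_BP) / HELICAL_REPEAT_BP
        base_rot = _rotation_between(
            system.anchor_in_dir[c + 1] / np.linalg.norm(system.anchor_in_dir[c + 1]),
            bond,
        )
        # stem-capable junctions keep the register twist when clear; at
        # floppy (non-stem) junctions the growth is steered away from the
        # existing mass so interrupted zigzag patches form an open necklace
        g = system.params.bend_modulus
        stem_next = g <= 0 or system.anchor_g[c + 1] > 1.5 * g
        centroid = core_pos[: c + 1].mean(axis=0)
        best = None
        for extra in (0.0, 0.7, -0.7, 1.4, -1.4, 2.1, -2.1, np.pi):
            R_try = _axis_angle(bond, twist + extra) @ base_rot
            p_try = a_in_next - R_try @ _ANCHOR_IN_BODY
            clearance = np.min(
                np.linalg.norm(core_pos[: c + 1] - p_try[None, :], axis=1)
            )
            score = min(clearance, 9.0)
            if not stem_next:
                away = p_try - centroid
                norm = np.linalg.norm(away)
                out_dir = R_try @ system.anchor_out_dir[c + 1]
                if norm > 1e-9:
                    score += 6.0 * float(np.dot(out_dir, away / norm))
            if best is None or score > best[0] + 1e-9:
                best = (score, R_try, p_try)
            if stem_next and clearance >= 7.0 and extra == 0.0:
                break
        core_rot[c + 1] = best[1]
        core_pos[c + 1] = best[2]
    state = State(core_pos=core_pos, core_rot=core_rot, bead_pos=bead_pos)
    sync_rigid_beads(system, state)
    return state


def sync_rigid_beads(system: System, state: State) -> None:
    """Recompute core-owned bead positions from the core poses."""
    for c in range(system.template.n_cores):
        s, e = system.core_block_start[c], system.core_block_end[c]
        state.bead_pos[s:e] = (
            state.core_pos[c][None, :] + system.body_pos[s:e] @ state.core_rot[c].T
        )


# ---------------------------------------------------------------------------
# energies (reference implementation, numpy; the sampler uses numba twins)


def _linker_nodes(system: System, state: State, li: int):
    c = li
    R_up, R_dn = state.core_rot[c], state.core_rot[c + 1]
    a_out = state.core_pos[c] + R_up @ _ANCHOR_OUT_BODY
    a_in = state.core_pos[c + 1] + R_dn @ _ANCHOR_IN_BODY
    d_out = R_up @ system.anchor_out_dir[c]
    d_in = R_dn @ system.anchor_in_dir[c + 1]
    nb = int(system.linker_len[li])
    s0 = int(system.linker_start[li])
    beads = state.bead_pos[s0 : s0 + nb]
    nodes = np.vstack([a_out, beads, a_in])
    return nodes, d_out, d_in, nb


def linker_bonded_energy(system: System, state: State, li: int) -> tuple[float, float]:
    """(stretch, bend) energy of one linker segment, kBT."""
    p = system.params
    nodes, d_out, d_in, nb = _linker_nodes(system, state, li)
    bonds = np.diff(nodes, axis=0)
    lengths = np.linalg.norm(bonds, axis=1)
    if nb == 0:
        e_str = 0.5 * p.zero_linker_k * (lengths[0] - p.zero_linker_nm) ** 2
    else:
        e_str = 0.5 * p.stretch_k * np.sum((lengths - p.bead_spacing_nm) ** 2)
    g = p.bend_modulus
    e_bend = 0.0
    if g > 0:
        units = bonds / np.maximum(lengths[:, None], 1e-12)
        cosines = np.sum(units[:-1] * units[1:], axis=1)
        e_bend += g * np.sum(1.0 - cosines)
        e_bend += system.anchor_g[li] * (1.0 - float(np.dot(d_out, units[0])))
        e_bend += system.anchor_g[li + 1] * (1.0 - float(np.dot(units[-1], d_in)))
    return float(e_str), float(e_bend)


def tail_bonded_energy(system: System, state: State) -> float:
    p = system.params
    if len(system.tail_chain_start) == 0:
        return 0.0
    e = 0.0
    for chain in range(len(system.tail_chain_start)):
        c = system.tail_chain_core[chain]
        attach = (
            state.core_pos[c] + state.core_rot[c] @ system.tail_chain_attach[chain]
        )
        s0 = system.tail_chain_start[chain]
        prev = attach
        for k in range(3):
            r = np.linalg.norm(state.bead_pos[s0 + k] - prev)
            e += 0.5 * p.tail_bond_k * (r - p.tail_bond_nm) ** 2
            prev = state.bead_pos[s0 + k]
    return float(e)


def _pair_tables(system: System):
    p = system.params
    sig = system.sigma_matrix()
    lam = p.debye_nm
    lam_dd = p.debye_dd_nm if p.debye_dd_nm is not None else lam
    cutoff = max(5.0 * max(lam, lam_dd), 2.0 * sig.max() * 2 ** (1.0 / 6.0))
    return sig, lam, lam_dd, cutoff


def _allowed_matrix(system: System) -> np.ndarray:
    """Upper-triangular boolean matrix of interacting pairs."""
    owner = system.owner
    l_id = system.linker_id
    slot = system.slot
    core_owned = owner >= 0
    same_owner = core_owned[:, None] & (owner[:, None] == owner[None, :])
    excl = core_owned[None, :] & (
        (owner[None, :] == system.excl1[:, None])
        | (owner[None, :] == system.excl2[:, None])
    )
    excl = excl | excl.T
    bonded = (
        (l_id[:, None] >= 0)
        & (l_id[:, None] == l_id[None, :])
        & (np.abs(slot[:, None] - slot[None, :]) == 1)
    )
    allowed = ~(same_owner | excl | bonded)
    np.fill_diagonal(allowed, False)
    return np.triu(allowed)


def nonbonded_energy(system: System, state: State) -> tuple[float, float, float]:
    """(elec excluding LH pairs, ev, elec involving LH); full pair scan."""
    sig, lam, lam_dd, cutoff = _pair_tables(system)
    p = system.params
    pos = state.bead_pos
    iu, ju = np.nonzero(_allowed_matrix(system))
    d = pos[iu] - pos[ju]
    r = np.linalg.norm(d, axis=1)
    near = r <= cutoff
    iu, ju, r = iu[near], ju[near], np.maximum(r[near], 1e-12)
    ti, tj = system.typ[iu], system.typ[ju]
    s = sig[ti, tj]
    e_ev = 0.0
    if p.ev_eps > 0:
        contact = r < s * 2 ** (1.0 / 6.0)
        sr6 = (s[contact] / r[contact]) ** 6
        ev = 4.0 * p.ev_eps * (sr6 * sr6 - sr6) + p.ev_eps
        e_ev = float(np.minimum(ev, p.ev_cap_kbt).sum())
    qq = system.q[iu] * system.q[ju]
    lam_ij = np.where((ti == T_LINKER) & (tj == T_LINKER), lam_dd, lam)
    re = np.maximum(r, p.elec_min_nm)
    e_pair = p.bjerrum_nm * qq * np.exp(-re / lam_ij) / re
    is_lh = (ti == T_LH) | (tj == T_LH)
    return float(e_pair[~is_lh].sum()), e_ev, float(e_pair[is_lh].sum())


def _allowed_py(system: System, i: int, j: int) -> bool:
    oi, oj = int(system.owner[i]), int(system.owner[j])
    if oi >= 0 and oi == oj:
        return False
    if oj >= 0 and (oj == system.excl1[i] or oj == system.excl2[i]):
        return False
    if oi >= 0 and (oi == system.excl1[j] or oi == system.excl2[j]):
        return False
    li, lj = int(system.linker_id[i]), int(system.linker_id[j])
    if li >= 0 and li == lj and abs(int(system.slot[i]) - int(system.slot[j])) == 1:
        return False
    return True


def total_energy(system: System, state: State) -> dict[str, float]:
    """Full energy with separated components, kBT."""
    e_str = e_bend = 0.0
    for li in range(system.template.n_cores - 1):
        s, b = linker_bonded_energy(system, state, li)
        e_str += s
        e_bend += b
    e_str += tail_bonded_energy(system, state)
    e_el, e_ev, e_lh = nonbonded_energy(system, state)
    comp = dict(stretch=e_str, bend=e_bend, elec=e_el, ev=e_ev, lh=e_lh)
    comp["total"] = sum(comp.values())
    if not np.isfinite(comp["total"]):
        raise FloatingPointError(f"non-finite energy: {comp}")
    return comp


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=False)
def _nb_seed(seed):
    # numba maintains its own RNG state; seeding must happen inside nopython
    np.random.seed(seed)


@njit(cache=False)
def _nb_allowed(i, j, owner, excl1, excl2, linker_id, slot):
    oi = owner[i]
    oj = owner[j]
    if oi >= 0 and oi == oj:
        return False
    if oj >= 0 and (oj == excl1[i] or oj == excl2[i]):
        return False
    if oi >= 0 and (oi == excl1[j] or oi == excl2[j]):
        return False
    li = linker_id[i]
    lj = linker_id[j]
    if li >= 0 and li == lj:
        ds = slot[i] - slot[j]
        if ds == 1 or ds == -1:
            return False
    return True


@njit(cache=False)
def _nb_pair_e(r, qi, qj, ti, tj, sig2, lam, lam_dd, bjerrum, ev_eps, cap, rmin):
    e = 0.0
    s2 = sig2[ti, tj]
    if ev_eps > 0.0 and r * r < s2 * 1.259921049894873:  # 2^(1/3)
        sr6 = (s2 / (r * r)) ** 3
        ev = 4.0 * ev_eps * (sr6 * sr6 - sr6) + ev_eps
        if ev > cap:
            ev = cap
        e += ev
    if qi != 0.0 and qj != 0.0:
        lam_ij = lam
        if ti == 0 and tj == 0:
            lam_ij = lam_dd
        re = r
        if re < rmin:
            re = rmin
        e += bjerrum * qi * qj * np.exp(-re / lam_ij) / re
    return e


@njit(cache=False)
def _nb_bead_external(
    i, pos, q, typ, owner, excl1, excl2, linker_id, slot,
    sig2, lam, lam_dd, bjerrum, ev_eps, cap, rmin, cutoff,
):
    e = 0.0
    n = pos.shape[0]
    xi = pos[i, 0]
    yi = pos[i, 1]
    zi = pos[i, 2]
    for j in range(n):
        if j == i:
            continue
        dx = xi - pos[j, 0]
        dy = yi - pos[j, 1]
        dz = zi - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > cutoff * cutoff or r2 < 1e-20:
            continue
        if not _nb_allowed(i, j, owner, excl1, excl2, linker_id, slot):
            continue
        e += _nb_pair_e(
            np.sqrt(r2), q[i], q[j], typ[i], typ[j],
            sig2, lam, lam_dd, bjerrum, ev_eps, cap, rmin,
        )
    return e


@njit(cache=False)
def _nb_set_external(
    in_moved, pos, q, typ, owner, excl1, excl2, linker_id, slot,
    sig2, lam, lam_dd, bjerrum, ev_eps, cap, rmin, cutoff,
):
    e = 0.0
    n = pos.shape[0]
    for i in range(n):
        if not in_moved[i]:
            continue
        for j in range(n):
            if in_moved[j]:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > cutoff * cutoff or r2 < 1e-20:
                continue
            if not _nb_allowed(i, j, owner, excl1, excl2, linker_id, slot):
                continue
            e += _nb_pair_e(
                np.sqrt(r2), q[i], q[j], typ[i], typ[j],
                sig2, lam, lam_dd, bjerrum, ev_eps, cap, rmin,
            )
    return e


@njit(cache=False)
def _nb_linker_bonded(
    li, bead_pos, core_pos, core_rot,
    linker_start, linker_len, anchor_in_body, anchor_out_body,
    anchor_in_dir, anchor_out_dir, anchor_g,
    l0, k_str, g, zl_len, zl_k,
):
    c = li
    nb = linker_len[li]
    n_nodes = nb + 2
    nodes = np.empty((n_nodes, 3))
    nodes[0] = core_pos[c] + core_rot[c] @ anchor_out_body
    for s in range(nb):
        nodes[1 + s] = bead_pos[linker_start[li] + s]
    nodes[n_nodes - 1] = core_pos[c + 1] + core_rot[c + 1] @ anchor_in_body
    d_out = core_rot[c] @ anchor_out_dir[c]
    d_in = core_rot[c + 1] @ anchor_in_dir[c + 1]
    e = 0.0
    prev_ux = d_out[0]
    prev_uy = d_out[1]
    prev_uz = d_out[2]
    first = True
    for b in range(n_nodes - 1):
        dx = nodes[b + 1, 0] - nodes[b, 0]
        dy = nodes[b + 1, 1] - nodes[b, 1]
        dz = nodes[b + 1, 2] - nodes[b, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if nb == 0:
            e += 0.5 * zl_k * (r - zl_len) ** 2
        else:
            e += 0.5 * k_str * (r - l0) ** 2
        if r < 1e-12:
            continue
        ux = dx / r
        uy = dy / r
        uz = dz / r
        if g > 0.0:
            gj = anchor_g[c] if first else g
            e += gj * (1.0 - (prev_ux * ux + prev_uy * uy + prev_uz * uz))
        first = False
        prev_ux = ux
        prev_uy = uy
        prev_uz = uz
    if g > 0.0:
        e += anchor_g[c + 1] * (
            1.0 - (prev_ux * d_in[0] + prev_uy * d_in[1] + prev_uz * d_in[2])
        )
    return e


@njit(cache=False)
def _nb_tail_bonded_chain(
    chain, bead_pos, core_pos, core_rot,
    tail_chain_core, tail_chain_attach, tail_chain_start,
    bond_len, bond_k,
):
    c = tail_chain_core[chain]
    attach = core_pos[c] + core_rot[c] @ tail_chain_attach[chain]
    s0 = tail_chain_start[chain]
    e = 0.0
    px = attach[0]
    py = attach[1]
    pz = attach[2]
    for k in range(3):
        dx = bead_pos[s0 + k, 0] - px
        dy = bead_pos[s0 + k, 1] - py
        dz = bead_pos[s0 + k, 2] - pz
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        e += 0.5 * bond_k * (r - bond_len) ** 2
        px = bead_pos[s0 + k, 0]
        py = bead_pos[s0 + k, 1]
        pz = bead_pos[s0 + k, 2]
    return e


@njit(cache=False)
def _nb_rotmat(ax, ay, az, angle):
    norm = np.sqrt(ax * ax + ay * ay + az * az)
    ax /= norm
    ay /= norm
    az /= norm
    c = np.cos(angle)
    s = np.sin(angle)
    one_c = 1.0 - c
    R = np.empty((3, 3))
    R[0, 0] = c + ax * ax * one_c
    R[0, 1] = ax * ay * one_c - az * s
    R[0, 2] = ax * az * one_c + ay * s
    R[1, 0] = ay * ax * one_c + az * s
    R[1, 1] = c + ay * ay * one_c
    R[1, 2] = ay * az * one_c - ax * s
    R[2, 0] = az * ax * one_c - ay * s
    R[2, 1] = az * ay * one_c + ax * s
    R[2, 2] = c + az * az * one_c
    return R


@njit(cache=False)
def _nb_sweep(
    # state (modified in place)
    bead_pos, core_pos, core_rot,
    # static topology
    q, typ, owner, excl1, excl2, linker_id, slot,
    linker_start, linker_len, core_block_start, core_block_end, body_pos,
    tail_chain_core, tail_chain_attach, tail_chain_start,
    anchor_in_body, anchor_out_body, anchor_in_dir, anchor_out_dir, anchor_g,
    mobile, bead_of_linker_ok,
    # pair tables
    sig2, lam, lam_dd, bjerrum, ev_eps, cap, rmin, cutoff,
    # bonded params
    l0, k_str, g, zl_len, zl_k, tail_bond_len, tail_bond_k,
    # move params
    n_moves, amp_bead, amp_core, amp_rot, p_core, p_pivot, p_crank,
    freeze_cores,
):
    """One batch of Metropolis moves.  Returns per-move-type statistics
    (attempts, accepts) x (bead, core, pivot, crank) and the accumulated
    energy change of accepted moves."""
    n = bead_pos.shape[0]
    nc = core_pos.shape[0]
    n_link = linker_len.shape[0]
    att = np.zeros(4, dtype=np.int64)
    acc = np.zeros(4, dtype=np.int64)
    de_total = 0.0
    n_mob = mobile.shape[0]
    in_moved = np.zeros(n, dtype=np.bool_)
    for _ in range(n_moves):
        u = np.random.random()
        if (not freeze_cores) and u < p_core:
            # rigid core translation + rotation
            att[1] += 1
            c = np.random.randint(0, nc)
            s0 = core_block_start[c]
            s1 = core_block_end[c]
            e_old = 0.0
            for i in range(s0, s1):
                in_moved[i] = True
            e_old += _nb_set_external(
                in_moved, bead_pos, q, typ, owner, excl1, excl2, linker_id,
                slot, sig2, lam, lam_dd, bjerrum, ev_eps, cap, rmin, cutoff,
            )
            if c > 0:
                e_old += _nb_linker_bonded(
                    c - 1, bead_pos, core_pos, core_rot, linker_start,
                    linker_len, anchor_in_body, anchor_out_body,
                    anchor_in_dir, anchor_out_dir, anchor_g, l0, k_str, g,
                    zl_len, zl_k,
                )
            if c < nc - 1:
                e_old += _nb_linker_bonded(
                    c, bead_pos, core_pos, core_rot, linker_start, linker_len,
                    anchor_in_body, anchor_out_body, anchor_in_dir,
                    anchor_out_dir, anchor_g, l0, k_str, g, zl_len, zl_k,
                )
            old_pos = core_pos[c].copy()
            old_rot = core_rot[c].copy()
            old_beads = bead_pos[s0:s1].copy()
            R = _nb_rotmat(
                np.random.normal(), np.random.normal(), np.random.normal(),
                (np.random.random() * 2.0 - 1.0) * amp_rot,
            )
            shift = np.empty(3)
            for d in range(3):
                shift[d] = (np.random.random() * 2.0 - 1.0) * amp_core
            core_rot[c] = R @ core_rot[c]
            for d in range(3):
                core_pos[c, d] = old_pos[d] + shift[d]
            # rigid transform of the block about the old core centre; tails
            # are flexible, so current offsets (not body coords) are rotated
            for i in range(s0, s1):
                rel = np.empty(3)
                for d in range(3):
                    rel[d] = old_beads[i - s0, d] - old_pos[d]
                newp = R @ rel
                for d in range(3):
                    bead_pos[i, d] = core_pos[c, d] + newp[d]
            e_new = _nb_set_external(
                in_moved, bead_pos, q, typ, owner, excl1, excl2, linker_id,
                slot, sig2, lam, lam_dd, bjerrum, ev_eps, cap, rmin, cutoff,
            )
            if c > 0:
                e_new += _nb_linker_bonded(
                    c - 1, bead_pos, core_pos, core_rot, linker_start,
                    linker_len, anchor_in_body, anchor_out_body,
                    anchor_in_dir, anchor_out_dir, anchor_g, l0, k_str, g,
                    zl_len, zl_k,
                )
            if c < nc - 1:
                e_new += _nb_linker_bonded(
                    c, bead_pos, core_pos, core_rot, linker_start, linker_len,
                    anchor_in_body, anchor_out_body, anchor_in_dir,
                    anchor_out_dir, anchor_g, l0, k_str, g, zl_len, zl_k,
                )
            de = e_new - e_old
            if de <= 0.0 or np.random.random() < np.exp(-de):
                acc[1] += 1
                de_total += de
            else:
                core_pos[c] = old_pos
                core_rot[c] = old_rot
                bead_pos[s0:s1] = old_beads
            for i in range(s0, s1):
                in_moved[i] = False
        elif u < p_core + p_pivot and n_link > 0 and bead_of_linker_ok:
            # pivot: rotate everything downstream of a random linker bead
            att[2] += 1
            li = np.random.randint(0, n_link)
            nb = linker_len[li]
            if nb == 0:
                continue
            s = np.random.randint(0, nb)
            pivot_idx = linker_start[li] + s
            n_moved = 0
            for i in range(n):
                mv = False
                if linker_id[i] == li and slot[i] > s:
                    mv = True
                elif linker_id[i] >= 0 and linker_id[i] > li:
                    mv = True
                elif owner[i] > li:
                    mv = True
                in_moved[i] = mv
                if mv:
                    n_moved += 1
            if n_moved == 0:
                for i in range(n):
                    in_moved[i] = False
                continue
            e_old = _nb_set_external(
                in_moved, bead_pos, q, typ, owner, excl1, excl2, linker_id,
                slot, sig2, lam, lam_dd, bjerrum, ev_eps, cap, rmin, cutoff,
            ) + _nb_linker_bonded(
                li, bead_pos, core_pos, core_rot, linker_start, linker_len,
                anchor_in_body, anchor_out_body, anchor_in_dir, anchor_out_dir,
                anchor_g, l0, k_str, g, zl_len, zl_k,
            )
            old_beads = bead_pos.copy()
            old_cpos = core_pos.copy()
            old_crot = core_rot.copy()
            R = _nb_rotmat(
                np.random.normal(), np.random.normal(), np.random.normal(),
                (np.random.random() * 2.0 - 1.0) * 0.5,
            )
            pvt = bead_pos[pivot_idx].copy()
            for i in range(n):
                if in_moved[i]:
                    rel = bead_pos[i] - pvt
                    newp = R @ rel
                    for d in range(3):
                        bead_pos[i, d] = pvt[d] + newp[d]
            for cc in range(li + 1, nc):
                rel = core_pos[cc] - pvt
                newp = R @ rel
                for d in range(3):
                    core_pos[cc, d] = pvt[d] + newp[d]
                core_rot[cc] = R @ core_rot[cc]
            e_new = _nb_set_external(
                in_moved, bead_pos, q, typ, owner, excl1, excl2, linker_id,
                slot, sig2, lam, lam_dd, bjerrum, ev_eps, cap, rmin, cutoff,
            ) + _nb_linker_bonded(
                li, bead_pos, core_pos, core_rot, linker_start, linker_len,
                anchor_in_body, anchor_out_body, anchor_in_dir, anchor_out_dir,
                anchor_g, l0, k_str, g, zl_len, zl_k,
            )
            de = e_new - e_old
            if de <= 0.0 or np.random.random() < np.exp(-de):
                acc[2] += 1
                de_total += de
            else:
                bead_pos[:] = old_beads
                core_pos[:] = old_cpos
                core_rot[:] = old_crot
            for i in range(n):
                in_moved[i] = False
        else:
            if n_mob == 0:
                continue
            i = mobile[np.random.randint(0, n_mob)]
            is_crank = (
                typ[i] == 2 and slot[i] == 1 and np.random.random() < p_crank
            )
            mtype = 3 if is_crank else 0
            att[mtype] += 1
            e_old = _nb_bead_external(
                i, bead_pos, q, typ, owner, excl1, excl2, linker_id, slot,
                sig2, lam, lam_dd, bjerrum, ev_eps, cap, rmin, cutoff,
            )
            li = linker_id[i]
            if li >= 0:
                e_old += _nb_linker_bonded(
                    li, bead_pos, core_pos, core_rot, linker_start, linker_len,
                    anchor_in_body, anchor_out_body, anchor_in_dir,
                    anchor_out_dir, anchor_g, l0, k_str, g, zl_len, zl_k,
                )
                chain = -1
            else:
                chain = 0
                for ch in range(tail_chain_start.shape[0]):
                    if tail_chain_start[ch] <= i < tail_chain_start[ch] + 3:
                        chain = ch
                        break
                e_old += _nb_tail_bonded_chain(
                    chain, bead_pos, core_pos, core_rot, tail_chain_core,
                    tail_chain_attach, tail_chain_start, tail_bond_len,
                    tail_bond_k,
                )
            old = bead_pos[i].copy()
            if is_crank:
                # rotate the middle tail bead about its neighbour axis
                a = bead_pos[i - 1]
                b = bead_pos[i + 1]
                axv = b - a
                if np.sqrt(axv[0] ** 2 + axv[1] ** 2 + axv[2] ** 2) < 1e-9:
                    att[mtype] -= 1
                    continue
                R = _nb_rotmat(
                    axv[0], axv[1], axv[2],
                    (np.random.random() * 2.0 - 1.0) * np.pi,
                )
                rel = bead_pos[i] - a
                newp = R @ rel
                for d in range(3):
                    bead_pos[i, d] = a[d] + newp[d]
            else:
                for d in range(3):
                    bead_pos[i, d] = old[d] + np.random.normal() * amp_bead
            e_new = _nb_bead_external(
                i, bead_pos, q, typ, owner, excl1, excl2, linker_id, slot,
                sig2, lam, lam_dd, bjerrum, ev_eps, cap, rmin, cutoff,
            )
            if li >= 0:
                e_new += _nb_linker_bonded(
                    li, bead_pos, core_pos, core_rot, linker_start, linker_len,
                    anchor_in_body, anchor_out_body, anchor_in_dir,
                    anchor_out_dir, anchor_g, l0, k_str, g, zl_len, zl_k,
                )
            else:
                e_new += _nb_tail_bonded_chain(
                    chain, bead_pos, core_pos, core_rot, tail_chain_core,
                    tail_chain_attach, tail_chain_start, tail_bond_len,
                    tail_bond_k,
                )
            de = e_new - e_old
            if de <= 0.0 or np.random.random() < np.exp(-de):
                acc[mtype] += 1
                de_total += de
            else:
                bead_pos[i] = old
    return att, acc, de_total


# ---------------------------------------------------------------------------
# sampler driver


@dataclass
class SamplerSettings:
    """Monte Carlo schedule; defaults are desk-scale (see run_mc docs)."""

    n_frames: int = 2000
    burn_in_sweeps: int = 2000
    sweeps_per_frame: int = 10
    bead_amp_nm: float = 0.6
    core_amp_nm: float = 1.0
    core_rot_deg: float = 25.0
    pivot_prob: float = 0.02
    crank_prob: float = 0.3
    freeze_cores: bool = False
    autotune: bool = True
    #: starting configuration: 'native' (idealized fiber) or 'open'
    start: str = "native"


@dataclass
class Ensemble:
    """Sampled configurations plus bead metadata and acceptance stats."""

    system: System
    core_positions: np.ndarray  # (n_frames, n_cores, 3)
    core_rotations: np.ndarray  # (n_frames, n_cores, 3, 3)
    bead_positions: np.ndarray  # (n_frames, n_beads, 3)
    seed: int
    replicate: int = 0
    acceptance: dict = field(default_factory=dict)
    energy_drift_check: float = 0.0  # |accumulated dE - (E_end - E_start)|

    @property
    def n_frames(self) -> int:
        return self.core_positions.shape[0]

    @property
    def frames(self) -> np.ndarray:  # for the PDB writer
        return self.bead_positions

    @property
    def bead_kinds(self) -> list[str]:
        return self.system.bead_kinds()


def _sweep_args(system: System, state: State, settings: SamplerSettings):
    p = system.params
    sig, lam, lam_dd, cutoff = _pair_tables(system)
    sig2 = sig**2
    n_mobile = max(len(system.mobile), 1)
    nc = system.template.n_cores
    n_moves_per_sweep = n_mobile + (0 if settings.freeze_cores else nc)
    p_core = 0.0 if settings.freeze_cores else nc / n_moves_per_sweep
    return dict(
        static=(
            system.q, system.typ, system.owner, system.excl1, system.excl2,
            system.linker_id, system.slot, system.linker_start,
            system.linker_len, system.core_block_start, system.core_block_end,
            system.body_pos, system.tail_chain_core, system.tail_chain_attach,
            system.tail_chain_start, _ANCHOR_IN_BODY, _ANCHOR_OUT_BODY,
            system.anchor_in_dir, system.anchor_out_dir, system.anchor_g,
            system.mobile, True,
            sig2, lam, lam_dd, p.bjerrum_nm, p.ev_eps, p.ev_cap_kbt,
            p.elec_min_nm, cutoff,
            p.bead_spacing_nm, p.stretch_k, p.bend_modulus, p.zero_linker_nm,
            p.zero_linker_k, p.tail_bond_nm, p.tail_bond_k,
        ),
        n_moves_per_sweep=n_moves_per_sweep,
        p_core=p_core,
    )


def run_mc(
    template: FiberTemplate,
    params: EnergyParams,
    settings: SamplerSettings | None = None,
    seed: int = 0,
    replicate: int = 0,
) -> Ensemble:
    """Metropolis sampling of one fiber; bit-reproducible for a fixed seed.

    Move mixture: single-bead displacement (linker/tail), rigid core
    translation+rotation, occasional pivot of the chain tail about a
    random linker bead, and crankshaft rotations of middle tail beads.
    Amplitudes are auto-tuned toward 30-50% acceptance during burn-in
    only.  Configurations are recorded every ``sweeps_per_frame`` sweeps
    after ``burn_in_sweeps``.
    """
    settings = settings or SamplerSettings()
    system = build_system(template, params)
    state = initial_configuration(system, settings.start)
    args = _sweep_args(system, state, settings)
    static = args["static"]
    n_moves = args["n_moves_per_sweep"]
    p_core = args["p_core"]

    _nb_seed(seed & 0x7FFFFFFF)
    amp_bead = settings.bead_amp_nm
    amp_core = settings.core_amp_nm
    amp_rot = np.deg2rad(settings.core_rot_deg)

    de_acc = 0.0
    e_start = total_energy(system, state)["total"]

    # burn-in with amplitude auto-tuning
    tune_block = max(settings.burn_in_sweeps // 10, 1)
    done = 0
    while done < settings.burn_in_sweeps:
        block = min(tune_block, settings.burn_in_sweeps - done)
        att, acc, de = _nb_sweep(
            state.bead_pos, state.core_pos, state.core_rot, *static,
            block * n_moves, amp_bead, amp_core, amp_rot, p_core,
            settings.pivot_prob, settings.crank_prob, settings.freeze_cores,
        )
        de_acc += de
        done += block
        if settings.autotune:
            if att[0] > 0:
                rate = acc[0] / att[0]
                if rate < 0.30:
                    amp_bead = max(amp_bead * 0.8, 0.02)
                elif rate > 0.50:
                    amp_bead = min(amp_bead * 1.25, 5.0)
            if att[1] > 0:
                rate = acc[1] / att[1]
                if rate < 0.30:
                    amp_core = max(amp_core * 0.8, 0.02)
                    amp_rot = max(amp_rot * 0.8, 0.01)
                elif rate > 0.50:
                    amp_core = min(amp_core * 1.25, 5.0)
                    amp_rot = min(amp_rot * 1.25, np.pi / 2)

    # production
    nc = template.n_cores
    n_beads = system.n_beads
    core_positions = np.zeros((settings.n_frames, nc, 3))
    core_rotations = np.zeros((settings.n_frames, nc, 3, 3))
    bead_positions = np.zeros((settings.n_frames, n_beads, 3))
    att_tot = np.zeros(4, dtype=np.int64)
    acc_tot = np.zeros(4, dtype=np.int64)
    for f in range(settings.n_frames):
        att, acc, de = _nb_sweep(
            state.bead_pos, state.core_pos, state.core_rot, *static,
            settings.sweeps_per_frame * n_moves, amp_bead, amp_core, amp_rot,
            p_core, settings.pivot_prob, settings.crank_prob,
            settings.freeze_cores,
        )
        de_acc += de
        att_tot += att
        acc_tot += acc
        core_positions[f] = state.core_pos
        core_rotations[f] = state.core_rot
        bead_positions[f] = state.bead_pos

    e_end = total_energy(system, state)["total"]
    drift = abs((e_start + de_acc) - e_end)
    acceptance = {
        name: (float(acc_tot[k] / att_tot[k]) if att_tot[k] else None)
        for k, name in enumerate(("bead", "core", "pivot", "crank"))
    }
    for name, rate in acceptance.items():
        if rate is not None and rate < 0.01:
            logger.warning(
                "acceptance rate for %s moves is %.3f (<1%%) after tuning; "
                "amplitudes: bead=%.3f core=%.3f rot=%.3f",
                name, rate, amp_bead, amp_core, amp_rot,
            )
    return Ensemble(
        system=system,
        core_positions=core_positions,
        core_rotations=core_rotations,
        bead_positions=bead_positions,
        seed=seed,
        replicate=replicate,
        acceptance=acceptance,
        energy_drift_check=drift,
    )


def replicate_seeds(master_seed: int, n_replicates: int) -> list[int]:
    """Documented seed-splitting rule for independent replicates."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n_replicates)]


def run_replicates(
    template: FiberTemplate,
    params: EnergyParams,
    settings: SamplerSettings | None = None,
    master_seed: int = 0,
    n_replicates: int = 20,
) -> list[Ensemble]:
    """Independent replicate ensembles via the seed-splitting rule."""
    out = []
    for r, s in enumerate(replicate_seeds(master_seed, n_replicates)):
        out.append(run_mc(template, params, settings, seed=s, replicate=r))
    return out
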