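"""Synthetic study inputs: LV shell phantoms, coronary trees, and FFR cohorts.

The generator emulates the structure the analysis assumes, at desk scale:

* a truncated half-ellipsoid shell standing in for the segmented LV
  myocardium (outer minus inner ellipsoid, cut above the base plane);
* three epicardial arteries (RCA, LAD, LCx) whose main branches run along
  the outer ellipsoid surface from base toward apex, with side branches;
* lesion geometry (MLD, RD, length) drawn from log-normal distributions
  whose medians and interquartile ranges match a typical intermediate-lesion
  FFR cohort (MLD 1.39 (1.04-1.69) mm, RD 2.65 (2.26-3.10) mm, length
  12.0 (7.6-15.8) mm);
* FFR from a stenosis pressure-loss model: hyperemic flow proportional to
  the subtended mass, a viscous (Poiseuille) term linear in flow and an
  expansion (Bernoulli) term quadratic in flow,

      Q  = q * MMAR
      dP = Kv * (L / MLD^4) * Q  +  Ke * (1/MLD^2 - 1/RD^2)^2 * Q^2
      FFR = clamp((Pa - dP) / Pa + eps, (0, 1]),   eps ~ N(0, sd).

All randomness flows from a single numpy Generator seeded from the config,
with draws in a documented order, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mask import MyocardiumMask
from .qca import LESION_COLUMNS, validate_lesion_table
from .territory import assign_voxels, compute_mmar, default_max_spacing
from .tree import CenterlineTree, LesionPoint, Node, densify_centerline, distal_sample_set


# ------------------------------------------------------------------- LV shell
@dataclass
class LvShellParams:
    """Truncated half-ellipsoid myocardial shell.

    Defaults give a ~120 ml LV wall (outer semi-axes 35 x 35 x 55 mm, 10 mm
    wall, truncated at 70% of the long axis measured from the apex) on a
    1 mm isotropic grid — plausible human LV volume at desk-scale runtime.
    """

    semi_axes: tuple = (35.0, 35.0, 55.0)   # outer (a, b, c) mm
    wall_thickness: float = 10.0            # mm
    truncation: float = 0.7                 # kept fraction of z-extent from apex
    spacing: float = 1.0                    # mm, isotropic

    def __post_init__(self) -> None:
        if self.wall_thickness >= min(self.semi_axes):
            raise ValueError("wall thickness must be below the smallest semi-axis")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if not (0 < self.truncation <= 1):
            raise ValueError("truncation fraction must lie in (0, 1]")

    @property
    def z_cut(self) -> float:
        c = self.semi_axes[2]
        return -c + self.truncation * 2 * c

    def analytic_volume_ml(self) -> float:
        """Ellipsoid-difference volume below the cut plane, in ml."""

        def below(a, b, c, z0):
            z0 = min(z0, c)
            f = lambda z: z - z ** 3 / (3 * c ** 2)
            return math.pi * a * b * (f(z0) - f(-c))

        a, b, c = self.semi_axes
        t = self.wall_thickness
        outer = below(a, b, c, self.z_cut)
        inner = below(a - t, b - t, c - t, self.z_cut)
        return (outer - inner) / 1000.0


def generate_lv_shell(params: LvShellParams) -> MyocardiumMask:
    """Voxelize the shell on an isotropic grid (deterministic)."""
    a, b, c = params.semi_axes
    t = params.wall_thickness
    sp = params.spacing
    lo = np.array([-a - sp, -b - sp, -c - sp])
    n = np.ceil((np.array([a, b, params.z_cut]) + sp - lo) / sp).astype(int) + 1
    affine = np.diag([sp, sp, sp, 1.0])
    affine[:3, 3] = lo
    i, j, k = np.meshgrid(*(np.arange(m) for m in n), indexing="ij")
    x = lo[0] + i * sp
    y = lo[1] + j * sp
    z = lo[2] + k * sp
    outer = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
    inner = (x / (a - t)) ** 2 + (y / (b - t)) ** 2 + (z / (c - t)) ** 2 <= 1.0
    grid = outer & ~inner & (z <= params.z_cut)
    if not grid.any():
        raise ValueError("shell parameters produce an empty mask")
    return MyocardiumMask(grid=grid, affine=affine)


# -------------------------------------------------------------- coronary tree
@dataclass
class TreeParams:
    """Epicardial three-artery tree on the outer ellipsoid surface.

    Main branches start near the base plane at fixed azimuths (LAD anterior,
    LCx lateral, RCA inferior-right) and descend toward the apex with a
    seeded azimuthal drift; side branches leave interior main-branch nodes
    and also descend apically at an azimuthal offset.
    """

    azimuth_deg: dict = field(
        default_factory=lambda: {"LAD": 0.0, "LCx": 120.0, "RCA": 240.0}
    )
    n_main_nodes: int = 25
    side_branches: dict = field(
        default_factory=lambda: {"LAD": 3, "LCx": 2, "RCA": 2}
    )
    n_side_nodes: int = 10
    side_extent: float = 0.5      # apical travel of a side branch (polar fraction)
    drift_deg: float = 35.0       # total azimuthal drift of a main branch
    seed: int = 0


def _surface_point(shell: LvShellParams, phi: float, theta: float) -> np.ndarray:
    a, b, c = shell.semi_axes
    return np.array(
        [a * math.sin(phi) * math.cos(theta),
         b * math.sin(phi) * math.sin(theta),
         -c * math.cos(phi)]
    )


def generate_coronary_tree(shell: LvShellParams, params: TreeParams) -> CenterlineTree:
    """Three rooted arteries with apically descending side branches.

    Every node lies exactly on the outer ellipsoid surface.  Reproducible
    from ``params.seed``; draws occur artery by artery in the fixed order
    RCA, LAD, LCx (roots first, then side branches proximal to distal).
    """
    rng = np.random.default_rng(params.seed)
    c = shell.semi_axes[2]
    phi_base = math.acos(-min(shell.z_cut, c * 0.999) / c)
    nodes: list[Node] = []
    next_id = 0

    for artery in ("RCA", "LAD", "LCx"):
        theta0 = math.radians(params.azimuth_deg[artery])
        drift = math.radians(params.drift_deg) * rng.uniform(0.6, 1.4)
        wiggle = rng.normal(0.0, 0.02, size=params.n_main_nodes)
        main_ids = []
        for i in range(params.n_main_nodes):
            t = i / (params.n_main_nodes - 1)
            phi = phi_base * (1.0 - 0.92 * t)      # base -> near apex
            theta = theta0 + drift * t + wiggle[i]
            nodes.append(
                Node(
                    node_id=next_id,
                    position=_surface_point(shell, phi, theta),
                    parent_id=None if i == 0 else main_ids[-1],
                    artery=artery,
                    branch="main",
                )
            )
            main_ids.append(next_id)
            next_id += 1

        n_side = params.side_branches[artery]
        if n_side:
            # attach side branches at evenly spread interior main nodes
            attach = np.linspace(3, params.n_main_nodes - 6, n_side).astype(int)
            for s, ai in enumerate(attach):
                sign = 1.0 if rng.random() < 0.5 else -1.0
                dtheta = sign * math.radians(rng.uniform(25.0, 45.0))
                t0 = ai / (params.n_main_nodes - 1)
                phi0 = phi_base * (1.0 - 0.92 * t0)
                theta_a = theta0 + drift * t0 + wiggle[ai]
                extent = params.side_extent * rng.uniform(0.7, 1.3)
                parent = main_ids[ai]
                for j in range(1, params.n_side_nodes + 1):
                    u = j / params.n_side_nodes
                    phi = phi0 * (1.0 - extent * u)
                    theta = theta_a + dtheta * u
                    nodes.append(
                        Node(
                            node_id=next_id,
                            position=_surface_point(shell, phi, theta),
                            parent_id=parent,
                            artery=artery,
                            branch=f"s{s + 1}",
                        )
                    )
                    parent = next_id
                    next_id += 1

    tree = CenterlineTree(nodes)
    tree.validate()
    return tree


# ------------------------------------------------------------------ FFR model
@dataclass
class FfrModelParams:
    """Stenosis pressure-loss model coefficients.

    ``pa`` aortic pressure (mmHg); ``q`` hyperemic flow per unit subtended
    mass (ml/min per ml of MMAR); ``kv`` viscous coefficient
    (mmHg·mm³·min/ml); ``ke`` expansion coefficient (mmHg·mm⁴·min²/ml²);
    ``noise_sd`` additive measurement noise on the FFR scale (0 disables).
    Defaults are calibrated so a cohort with the default geometry yields
    roughly 40% of lesions at FFR <= 0.8 (median FFR ~0.85).
    """

    pa: float = 90.0
    q: float = 1.5
    kv: float = 0.045
    ke: float = 0.018
    noise_sd: float = 0.045

    def __post_init__(self) -> None:
        if self.pa <= 0:
            raise ValueError("aortic pressure must be positive")
        if min(self.q, self.kv, self.ke, self.noise_sd) < 0:
            raise ValueError("model coefficients must be non-negative")


def simulate_ffr(
    mmar_ml: float,
    mld: float,
    rd: float,
    length: float,
    params: FfrModelParams,
    rng: np.random.Generator | None = None,
) -> float:
    """FFR from the viscous + expansion pressure-loss model (see module docs)."""
    if mld <= 0 or rd <= 0 or length <= 0 or mmar_ml < 0:
        raise ValueError("invalid lesion geometry")
    if mld > rd:
        raise ValueError("MLD may not exceed the reference diameter")
    flow = params.q * mmar_ml
    dp = (
        params.kv * (length / mld ** 4) * flow
        + params.ke * (1.0 / mld ** 2 - 1.0 / rd ** 2) ** 2 * flow ** 2
    )
    ffr = (params.pa - dp) / params.pa
    if params.noise_sd > 0:
        if rng is None:
            raise ValueError("noise requires a random generator")
        ffr += rng.normal(0.0, params.noise_sd)
    return float(min(1.0, max(1e-6, ffr)))


# --------------------------------------------------------------------- cohort
@dataclass
class LesionDistributionParams:
    """Log-normal lesion geometry and placement frequencies.

    (mu, sigma) are on the log scale; medians/IQRs target an intermediate-
    lesion cohort.  Lesions sit on main branches at a relative arc position
    drawn uniformly from ``position_range`` (culprit lesions cluster in the
    proximal-to-mid vessel); ``proximal_cutoff`` is the relative arc below
    which a lesion is labelled proximal.
    """

    mld_log: tuple = (math.log(1.39), 0.360)
    rd_log: tuple = (math.log(2.65), 0.234)
    length_log: tuple = (math.log(12.0), 0.543)
    artery_probs: dict = field(
        default_factory=lambda: {"RCA": 0.18, "LAD": 0.61, "LCx": 0.21}
    )
    position_range: tuple = (0.0, 0.25)
    proximal_cutoff: float = 0.09


def generate_cohort(
    n_lesions: int,
    shell: MyocardiumMask,
    tree: CenterlineTree,
    geom: LesionDistributionParams | None = None,
    ffr_params: FfrModelParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a lesion cohort with geometrically computed MMAR.

    Per lesion, in draw order: artery, relative main-branch position, RD,
    MLD (pair redrawn until MLD < RD), length, then the FFR noise term.
    The territory label map is computed once for the tree; each lesion's
    MMAR sums the voxel counts of its downstream samples.
    """
    if n_lesions < 0:
        raise ValueError("n_lesions must be >= 0")
    geom = geom or LesionDistributionParams()
    ffr_params = ffr_params or FfrModelParams()
    rng = np.random.default_rng(seed)

    st = densify_centerline(tree, default_max_spacing(shell))
    labels = assign_voxels(shell, st)
    arteries = list(geom.artery_probs)
    probs = np.array([geom.artery_probs[a] for a in arteries])
    probs = probs / probs.sum()
    main_len = {
        a: float(st.arc[(st.artery == a) & (st.branch == "main")].max())
        for a in arteries
    }

    rows = []
    for i in range(n_lesions):
        artery = arteries[rng.choice(len(arteries), p=probs)]
        u = rng.uniform(*geom.position_range)
        rd = float(rng.lognormal(*geom.rd_log))
        mld = float(rng.lognormal(*geom.mld_log))
        while mld >= rd:
            rd = float(rng.lognormal(*geom.rd_log))
            mld = float(rng.lognormal(*geom.mld_log))
        length = float(rng.lognormal(*geom.length_log))
        lesion = LesionPoint(artery=artery, anchor=("main", u * main_len[artery]))
        distal = distal_sample_set(st, lesion)
        mmar_ml, pct_mmar, _ = compute_mmar(labels, distal, shell)
        ffr = simulate_ffr(mmar_ml, mld, rd, length, ffr_params, rng)
        rows.append(
            {
                "lesion_id": i,
                "artery": artery,
                "proximal": bool(u < geom.proximal_cutoff),
                "mld_mm": mld,
                "rd_mm": rd,
                "length_mm": length,
                "ds_pct": (1.0 - mld / rd) * 100.0,
                "mmar_ml": mmar_ml,
                "pct_mmar": pct_mmar,
                "ffr": ffr,
            }
        )
    df = pd.DataFrame(rows, columns=LESION_COLUMNS)
    if n_lesions:
        df = validate_lesion_table(df)
    return df
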