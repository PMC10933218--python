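"""Synthetic abdominal CT phantoms and simulated cohort tables.

The phantom emulates the slab of anatomy the analysis actually uses —
the superior boundary of L1 down to the pubic symphysis — as nested
elliptical compartments on each axial slice: a subcutaneous fat annulus
just under the skin, an abdominal-wall muscle ring, an interior cavity
at soft-tissue attenuation with a vertebral bone disk, and visceral fat
placed inside the cavity. Compartment HU means put both fat classes
inside the standard fat window (−190..−30 HU) and everything else
outside it, with additive Gaussian noise.

The craniocaudal visceral fat profile is the controllable feature of
interest: a density over the normalized position t ∈ [0, 1] (t = 0 at
L1-1, t = 1 at the pubic symphysis) scaled to a total VAT volume. The
``beta`` family uses the Beta(1 + c, 1) density, whose mass shifts
toward the caudal (lower lumbar / pelvic) end as the concentration c
grows, mimicking the concentrated distribution seen in Crohn's disease;
c = 0 recovers the uniform profile typical of ulcerative colitis and
controls.

Per slice, the requested fat area is realized exactly (to one pixel) by
taking the N cavity pixels nearest a jittered, anisotropically stretched
blob centre, so ground-truth per-slice areas follow the profile within
voxelization error and total volume is conserved to well under 2%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .anatomy import LandmarkTable, REQUIRED_LABELS
from .core import CTVolume, LabelMask, Spacing

#: default compartment attenuation: mean HU and Gaussian noise SD
DEFAULT_HU = {
    "air": (-1000.0, 10.0),
    "sat": (-105.0, 10.0),
    "vat": (-100.0, 10.0),
    "muscle": (40.0, 10.0),
    "bone": (400.0, 10.0),
}

#: reference fat window used to validate compartment placement
_FAT_LOW, _FAT_HIGH = -190.0, -30.0


def default_landmarks() -> LandmarkTable:
    """Landmarks of the default phantom: 35 mm vertebrae, 175 mm lumbar span."""
    return LandmarkTable(
        {
            "L1-1": 315.0,
            "L2-1": 280.0,
            "L3-1": 245.0,
            "L4-1": 210.0,
            "L5-1": 175.0,
            "L5-5": 140.0,
            "pubic_symphysis": 20.0,
        }
    )


@dataclass
class ProfileSpec:
    """Craniocaudal VAT density over normalized position t ∈ [0, 1].

    family
        ``uniform`` — constant density; ``linear`` — density
        1 + c·(t − 1/2), tilting mass caudally; ``beta`` — Beta(1 + c, 1)
        density ∝ t^c concentrating mass at the caudal end.
    concentration
        Dimensionless ≥ 0; 0 reduces every family to uniform.
    normalization
        Total VAT volume in cm³ the profile integrates to.
    """

    family: str = "uniform"
    concentration: float = 0.0
    normalization: float = 1500.0

    def __post_init__(self) -> None:
        if self.family not in ("uniform", "linear", "beta"):
            raise ValueError(f"unknown profile family {self.family!r}")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.family == "linear" and self.concentration > 2:
            raise ValueError("linear profile needs concentration <= 2 for non-negative density")
        if self.normalization < 0:
            raise ValueError("total VAT volume must be non-negative")

    def cumulative(self, t: np.ndarray) -> np.ndarray:
        """CDF of the unit-mass density at normalized positions t (clipped to [0,1])."""
        t = np.clip(np.asarray(t, dtype=float), 0.0, 1.0)
        c = self.concentration
        if self.family == "uniform" or c == 0:
            return t
        if self.family == "linear":
            return t + c * (t**2 / 2 - t / 2)
        return t ** (c + 1)


@dataclass
class PhantomSpec:
    """Geometry, attenuation, profile, and seed of one synthetic scan.

    The body cross-section is an ellipse with semi-axes
    (``body_radius``, ``body_aspect * body_radius``) mm in (x, y). The
    subcutaneous annulus is ``sat_thickness`` mm thick, followed by an
    abdominal-wall ring of ``muscle_thickness`` mm; the remainder is the
    visceral cavity.
    """

    grid_shape: tuple[int, int, int] = (120, 224, 300)
    voxel_spacing: Spacing = (3.0, 1.0, 1.0)
    body_radius: float = 140.0
    body_aspect: float = 0.72
    sat_thickness: float = 15.0
    muscle_thickness: float = 10.0
    vat_total_volume: float = 1500.0
    vat_profile: ProfileSpec = field(default_factory=ProfileSpec)
    hu_values: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_HU))
    landmarks: LandmarkTable = field(default_factory=default_landmarks)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid shape must be positive")
        if self.vat_total_volume < 0:
            raise ValueError("requested VAT volume must be non-negative")
        if min(self.body_radius, self.sat_thickness, self.muscle_thickness) <= 0:
            raise ValueError("geometry lengths must be positive")
        for comp in DEFAULT_HU:
            if comp not in self.hu_values:
                raise ValueError(f"hu_values missing compartment {comp!r}")
        for comp in ("sat", "vat"):
            mu = self.hu_values[comp][0]
            if not _FAT_LOW <= mu <= _FAT_HIGH:
                raise ValueError(f"{comp} mean HU {mu} falls outside the fat window")
        for comp in ("air", "muscle", "bone"):
            mu = self.hu_values[comp][0]
            if _FAT_LOW <= mu <= _FAT_HIGH:
                raise ValueError(f"{comp} mean HU {mu} falls inside the fat window")

        nz, ny, nx = self.grid_shape
        sz, sy, sx = self.voxel_spacing
        if self.landmarks["L1-1"] >= nz * sz or self.landmarks["pubic_symphysis"] < 0:
            raise ValueError(
                "grid does not cover the analysis range L1-1 to pubic symphysis: "
                f"z extent [0, {nz * sz}) mm vs landmarks "
                f"[{self.landmarks['pubic_symphysis']}, {self.landmarks['L1-1']}] mm"
            )
        rx, ry = self.body_radius, self.body_aspect * self.body_radius
        if 2 * rx >= nx * sx or 2 * ry >= ny * sy:
            raise ValueError(
                f"grid too small to contain the body ellipse: needs "
                f"{2 * rx:.0f}×{2 * ry:.0f} mm, grid is {nx * sx:.0f}×{ny * sy:.0f} mm"
            )
        if self.body_radius <= self.sat_thickness + self.muscle_thickness + 10:
            raise ValueError("body radius leaves no visceral cavity")

    @property
    def cavity_semiaxes(self) -> tuple[float, float]:
        wall = self.sat_thickness + self.muscle_thickness
        return self.body_radius - wall, self.body_aspect * self.body_radius - wall


def _ellipse(yy: np.ndarray, xx: np.ndarray, rx: float, ry: float) -> np.ndarray:
    return (xx / rx) ** 2 + (yy / ry) ** 2 <= 1.0


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[CTVolume, dict[str, LabelMask], LandmarkTable]:
    """Render one phantom: HU volume, ground-truth masks, landmark table.

    Returns
    -------
    volume, masks, landmarks
        ``masks`` holds boolean ground truth for ``"vat"``, ``"sat"``
        and ``"body"``. Identical spec (including seed) gives
        bit-identical arrays.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.grid_shape
    sz, sy, sx = spec.voxel_spacing
    rx, ry = spec.body_radius, spec.body_aspect * spec.body_radius

    y = (np.arange(ny) - (ny - 1) / 2) * sy
    x = (np.arange(nx) - (nx - 1) / 2) * sx
    yy, xx = np.meshgrid(y, x, indexing="ij")

    body2d = _ellipse(yy, xx, rx, ry)
    inner = _ellipse(yy, xx, rx - spec.sat_thickness, ry - spec.sat_thickness)
    rcx, rcy = spec.cavity_semiaxes
    cavity = _ellipse(yy, xx, rcx, rcy)
    sat2d = body2d & ~inner
    muscle2d = inner & ~cavity

    # vertebral body: bone disk at the posterior cavity margin
    spine_r = min(15.0, 0.35 * rcy)
    spine_cy = 0.65 * rcy
    spine2d = ((xx / spine_r) ** 2 + ((yy - spine_cy) / spine_r) ** 2 <= 1.0) & cavity
    margin = ((xx / (spine_r + 3)) ** 2 + ((yy - spine_cy) / (spine_r + 3)) ** 2 <= 1.0) & cavity
    candidates2d = cavity & ~margin

    cav_y = yy[candidates2d]
    cav_x = xx[candidates2d]
    cand_idx = np.flatnonzero(candidates2d.ravel())
    n_candidates = cand_idx.size
    px_area = sy * sx

    # per-slice VAT pixel budget from the profile CDF over each slice's t-range
    z_lo = np.arange(nz) * sz
    z_hi = z_lo + sz
    z_top = spec.landmarks["L1-1"]
    z_bot = spec.landmarks["pubic_symphysis"]
    span = z_top - z_bot
    # z decreases craniocaudally, t increases: t = (z_top - z)/span
    t_lo = (z_top - z_hi) / span
    t_hi = (z_top - z_lo) / span
    profile = replace(spec.vat_profile, normalization=spec.vat_total_volume)
    frac = profile.cumulative(t_hi) - profile.cumulative(t_lo)
    slice_vol_mm3 = frac * spec.vat_total_volume * 1000.0
    n_px = np.rint(slice_vol_mm3 / (sz * px_area)).astype(int)
    if n_px.max(initial=0) > n_candidates:
        raise ValueError(
            f"requested VAT volume needs {n_px.max()} pixels on one slice but the "
            f"cavity offers only {n_candidates}; enlarge the body or reduce the volume"
        )

    vat = np.zeros((nz, ny, nx), dtype=bool)
    flat = vat.reshape(nz, -1)
    for i in range(nz):
        n = n_px[i]
        # one rng draw per slice regardless of n keeps the stream aligned
        cy_j, cx_j = rng.normal(0.0, 5.0, size=2)
        aspect = rng.uniform(0.75, 1.3)
        if n == 0:
            continue
        d2 = ((cav_x - cx_j) / aspect) ** 2 + ((cav_y - cy_j) * aspect) ** 2
        take = np.argpartition(d2, n - 1)[:n]
        flat[i, cand_idx[take]] = True

    mu = np.full((nz, ny, nx), spec.hu_values["air"][0], dtype=np.float32)
    sd = np.full((nz, ny, nx), spec.hu_values["air"][1], dtype=np.float32)
    for comp, region2d in (("sat", sat2d), ("muscle", muscle2d | cavity), ("bone", spine2d)):
        m, s = spec.hu_values[comp]
        mu[:, region2d] = m
        sd[:, region2d] = s
    m, s = spec.hu_values["vat"]
    mu[vat] = m
    sd[vat] = s
    data = mu + sd * rng.standard_normal((nz, ny, nx)).astype(np.float32)

    masks = {
        "vat": LabelMask(vat, spec.voxel_spacing),
        "sat": LabelMask(np.broadcast_to(sat2d, (nz, ny, nx)).copy(), spec.voxel_spacing),
        "body": LabelMask(np.broadcast_to(body2d, (nz, ny, nx)).copy(), spec.voxel_spacing),
    }
    return CTVolume(data, spec.voxel_spacing), masks, spec.landmarks


# ---------------------------------------------------------------------------
# cohort simulation

#: recognised cohort variables and their default distribution family
COHORT_VARIABLES = {
    "cv_pct": "normal",
    "vat_volume_cm3": "normal",
    "age_years": "normal",
    "sex_male": "bernoulli",
    "perianal_disease": "bernoulli",
    "crp_mg_l": "lognormal",
    "esr_mm_hr": "lognormal",
}


@dataclass
class GroupSpec:
    label: str
    n: int
    variables: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"group {self.label!r}: n must be positive")
        for name, params in self.variables.items():
            if name not in COHORT_VARIABLES:
                raise ValueError(
                    f"unknown cohort variable {name!r}; known: {sorted(COHORT_VARIABLES)}"
                )
            if "sd" in params and params["sd"] < 0:
                raise ValueError(f"{name}: sd must be >= 0")
            if "p" in params and not 0 <= params["p"] <= 1:
                raise ValueError(f"{name}: probability must be in [0, 1]")


@dataclass
class CohortSpec:
    """Per-group marginal distributions for the simulated cohort table.

    Variables are sampled independently within subject; continuous
    variables are normal (``mean``/``sd``), binary ones Bernoulli
    (``p``), and right-skewed laboratory values lognormal
    (``median``/``q1``/``q3`` matched on the log scale).
    """

    groups: list[GroupSpec]
    seed: int = 0

    @classmethod
    def ibd_defaults(cls, arm: str = "semiautomatic", seed: int = 0) -> "CohortSpec":
        """Three-group IBD cohort with published marginal parameters.

        ``arm`` selects which segmentation arm's CV distribution is
        simulated (``semiautomatic`` or ``automatic``).
        """
        cv = {
            "semiautomatic": ((29.42, 15.54), (25.69, 12.61), (23.42, 15.62)),
            "automatic": ((29.73, 14.67), (26.23, 12.47), (23.96, 11.09)),
        }[arm]
        vol = ((1584.95, 1128.31), (1855.30, 1326.12), (2470.91, 1646.42))
        age = ((33.5, 12.0), (45.0, 14.0), (41.0, 15.0))
        sex_p = (255 / 365, 138 / 241, 80 / 166)
        perianal_p = (129 / 344, 18 / 237, 0.0)
        crp = ((22.10, 6.42, 55.78), (6.7, 1.8, 21.3), (5.0, 1.5, 15.0))
        esr = ((27.0, 10.0, 52.0), (16.0, 7.0, 38.0), (12.0, 5.0, 25.0))
        ns = (365, 241, 166)
        groups = []
        for i, label in enumerate(("CD", "UC", "control")):
            groups.append(
                GroupSpec(
                    label=label,
                    n=ns[i],
                    variables={
                        "cv_pct": {"mean": cv[i][0], "sd": cv[i][1]},
                        "vat_volume_cm3": {"mean": vol[i][0], "sd": vol[i][1]},
                        "age_years": {"mean": age[i][0], "sd": age[i][1]},
                        "sex_male": {"p": sex_p[i]},
                        "perianal_disease": {"p": perianal_p[i]},
                        "crp_mg_l": {"median": crp[i][0], "q1": crp[i][1], "q3": crp[i][2]},
                        "esr_mm_hr": {"median": esr[i][0], "q1": esr[i][1], "q3": esr[i][2]},
                    },
                )
            )
        return cls(groups=groups, seed=seed)


def _draw(rng: np.random.Generator, family: str, params: dict[str, float], n: int) -> np.ndarray:
    if "p" in params:
        return (rng.random(n) < params["p"]).astype(int)
    if "median" in params:
        mu = math.log(params["median"])
        sigma = (math.log(params["q3"]) - math.log(params["q1"])) / (2 * 0.674489750196082)
        return np.exp(rng.normal(mu, sigma, n))
    if "mean" in params:
        return rng.normal(params["mean"], params["sd"], n)
    raise ValueError(f"cannot interpret distribution parameters {params!r} for a {family} variable")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one subject row per group member from the marginal distributions."""
    rng = np.random.default_rng(spec.seed)
    frames = []
    for g in spec.groups:
        cols: dict[str, np.ndarray] = {}
        for name, params in g.variables.items():
            cols[name] = _draw(rng, COHORT_VARIABLES[name], params, g.n)
        df = pd.DataFrame(cols)
        df.insert(0, "group", g.label)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "subject_id", [f"S{i:05d}" for i in range(len(out))])
    return out
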