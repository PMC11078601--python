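"""Surrogate reaction system: a 2-D Langevin model of anion--cation recombination.

The model stands in for an expensive quantum-chemical propagator while keeping
the statistical topology the analysis machinery assumes: a diffusional
encounter from large separations, an ion-pair shell of "site" wells on a
contact ring (the peripheral carbons of the cation's phenyl propellers), an
activation barrier, and a deep product well at the central carbon.

Geometry is polar: the configuration is the anion position ``(r, theta)``
relative to the cation center, in reduced Angstrom-like units.  Energies are
in units of kT and time in reduced picoseconds.  Macrostate thresholds are
fixed by convention:

* unassociated: r > 10
* ion pair:     2.25 <= r <= 5
* product:      r < 1.6

Regions between those bands carry no label (buffer zones).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

__all__ = [
    "R_UNASSOCIATED",
    "R_ION_PAIR_OUTER",
    "R_ION_PAIR_INNER",
    "R_PRODUCT",
    "MACROSTATES",
    "SurrogateParams",
    "Configuration",
    "make_surrogate",
    "potential",
    "potential_xy",
    "force_xy",
    "propagate",
    "propagate_batch",
    "classify_macrostate",
    "classify_r",
    "nearest_site",
    "site_labels_xy",
    "initial_pool",
    "generate_label_sequences",
]

# State-definition distance thresholds (reduced Angstrom).
R_UNASSOCIATED = 10.0   # r >  10   -> unassociated reactants
R_ION_PAIR_OUTER = 5.0  # 2.25 <= r <= 5 -> ion-pair intermediate
R_ION_PAIR_INNER = 2.25
R_PRODUCT = 1.6         # r <  1.6  -> covalent product (recycling threshold)

#: Ordered macrostate labels; classify_r returns indices into this tuple.
MACROSTATES = ("unassociated", "ion_pair", "product")


@dataclass(frozen=True)
class Configuration:
    """Anion position relative to the cation center, polar (r, theta)."""

    r: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.r) or self.r < 0:
            raise ValueError(f"radius must be finite and >= 0, got {self.r}")
        object.__setattr__(self, "theta", float(self.theta) % (2.0 * math.pi))

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.r * math.cos(self.theta), self.r * math.sin(self.theta)])

    @classmethod
    def from_xy(cls, x: float, y: float) -> "Configuration":
        return cls(math.hypot(x, y), math.atan2(y, x))


@dataclass(frozen=True)
class SurrogateParams:
    """Parameters of the surrogate free-energy landscape and its dynamics.

    The landscape is the sum of

    * a screened long-range attraction ``-c * exp(-s/lambda)/s`` with the
      softened distance ``s = sqrt(r^2 + core^2)`` (smooth at the origin,
      indistinguishable from zero at large r),
    * Gaussian site wells of per-label depth on the contact ring,
    * a Gaussian product well at the origin,
    * a Gaussian barrier ring between product and contact radii, whose
      amplitude is calibrated at construction so the realized
      ion-pair -> product barrier equals ``barrier_height``,
    * a soft quartic confining wall (the finite simulation box).
    """

    n_sites: int = 6
    site_angles: tuple[float, ...] = ()
    site_labels: tuple[str, ...] = ("O", "P", "O", "P", "O", "P")
    site_well_depth: tuple[tuple[str, float], ...] = (("O", 2.0), ("P", 2.0))
    r_contact: float = 3.5
    r_product: float = 1.3
    barrier_height: float = 3.0
    barrier_radius: float = 1.8
    barrier_width: float = 0.22
    site_width: float = 0.55
    site_well_width: tuple[tuple[str, float], ...] = ()  # per-label override
    product_depth: float = 12.0
    product_width: float = 0.6
    long_range_strength: float = 6.0
    screening_length: float = 4.0
    core_radius: float = 1.0
    wall_radius: float = 60.0
    wall_strength: float = 0.05
    site_cutoff_radius: float = 4.65  # site wells fade out before the 5 A
    site_cutoff_width: float = 0.12   # collision boundary: encounter kinetics
    kT: float = 1.0                   # is identical across presets
    gamma: float = 1.0
    dt: float = 0.002
    barrier_amplitude: float = field(default=-1.0, compare=False)

    def __post_init__(self) -> None:
        if self.barrier_height <= 0:
            raise ValueError("barrier_height must be positive")
        if not (self.r_product < R_ION_PAIR_INNER < self.r_contact
                < R_ION_PAIR_OUTER < R_UNASSOCIATED):
            raise ValueError(
                "geometry must satisfy r_product < 2.25 < r_contact < 5 < 10; "
                f"got r_product={self.r_product}, r_contact={self.r_contact}")
        if not (self.r_product < self.barrier_radius < R_ION_PAIR_INNER):
            raise ValueError("barrier ring must lie between product and ion-pair radii")
        angles = self.site_angles
        if not angles:
            angles = tuple(2.0 * math.pi * k / self.n_sites for k in range(self.n_sites))
            object.__setattr__(self, "site_angles", angles)
        if len(angles) != self.n_sites or len(self.site_labels) != self.n_sites:
            raise ValueError("site_angles and site_labels must have n_sites entries")
        wrapped = np.mod(angles, 2.0 * math.pi)
        if len(np.unique(np.round(wrapped, 9))) != self.n_sites:
            raise ValueError("site angles must be distinct modulo 2*pi")
        depths = dict(self.site_well_depth)
        missing = set(self.site_labels) - set(depths)
        if missing:
            raise ValueError(f"site_well_depth missing labels {sorted(missing)}")
        if any(p <= 0 for p in (self.dt, self.gamma)) or self.kT < 0:
            raise ValueError("dt and gamma must be positive, kT non-negative")
        if self.barrier_amplitude < 0:
            object.__setattr__(self, "barrier_amplitude", _calibrate_barrier(self))

    # -- derived geometry -------------------------------------------------
    @property
    def depths(self) -> dict[str, float]:
        return dict(self.site_well_depth)

    @property
    def site_xy(self) -> np.ndarray:
        """(n_sites, 2) Cartesian site-well centers on the contact ring."""
        a = np.asarray(self.site_angles)
        return self.r_contact * np.stack([np.cos(a), np.sin(a)], axis=1)

    @property
    def site_depth_array(self) -> np.ndarray:
        d = self.depths
        return np.array([d[lab] for lab in self.site_labels])

    @property
    def site_width_array(self) -> np.ndarray:
        w = dict(self.site_well_width)
        return np.array([w.get(lab, self.site_width) for lab in self.site_labels])

    @property
    def label_alphabet(self) -> tuple[str, ...]:
        """Site-label alphabet including the central carbon T."""
        seen: list[str] = ["T"]
        for lab in self.site_labels:
            if lab not in seen:
                seen.append(lab)
        return tuple(seen)


def _landscape_xy(params: SurrogateParams, x, y, *, barrier_amplitude=None):
    """Vectorized potential energy (kT) at Cartesian points, without validation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r2 = x * x + y * y
    r = np.sqrt(r2)
    amp = params.barrier_amplitude if barrier_amplitude is None else barrier_amplitude

    s = np.sqrt(r2 + params.core_radius ** 2)
    u = -params.long_range_strength * np.exp(-s / params.screening_length) / s
    u = u - params.product_depth * np.exp(-r2 / (2.0 * params.product_width ** 2))
    u = u + amp * np.exp(-((r - params.barrier_radius) ** 2)
                         / (2.0 * params.barrier_width ** 2))
    centers = params.site_xy
    depths = params.site_depth_array
    widths = params.site_width_array
    # radial envelope: wells act only inside the contact shell, so the
    # landscape beyond ~4.8 is identical for every preset
    env = 0.5 * (1.0 - np.tanh((r - params.site_cutoff_radius)
                               / params.site_cutoff_width))
    for (cx, cy), d, sw in zip(centers, depths, widths):
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        u = u - d * env * np.exp(-d2 / (2.0 * sw ** 2))
    over = np.maximum(r - params.wall_radius, 0.0)
    u = u + params.wall_strength * over ** 4
    return u


def force_xy(params: SurrogateParams, xy: np.ndarray) -> np.ndarray:
    """Vectorized force -grad U at Cartesian points, shape (n, 2)."""
    xy = np.asarray(xy, dtype=float)
    x, y = xy[..., 0], xy[..., 1]
    r2 = x * x + y * y
    r = np.sqrt(r2)

    # screened attraction: dU/ds * (x, y)/s with s = sqrt(r^2 + a^2)
    s = np.sqrt(r2 + params.core_radius ** 2)
    c, lam = params.long_range_strength, params.screening_length
    dUds = c * np.exp(-s / lam) * (1.0 / (lam * s) + 1.0 / (s * s))
    fx = -dUds * x / s
    fy = -dUds * y / s

    # product well (smooth function of r^2)
    dp = params.product_depth / params.product_width ** 2
    g = dp * np.exp(-r2 / (2.0 * params.product_width ** 2))
    fx = fx - g * x
    fy = fy - g * y

    # barrier ring; radial, guarded at the origin where the tail is ~0 anyway
    rb, wb = params.barrier_radius, params.barrier_width
    bump = params.barrier_amplitude * np.exp(-((r - rb) ** 2) / (2.0 * wb ** 2))
    radial = bump * (r - rb) / wb ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        inv_r = np.where(r > 1e-12, 1.0 / np.maximum(r, 1e-12), 0.0)
    fx = fx + radial * x * inv_r
    fy = fy + radial * y * inv_r

    # site wells (attractive) / patches (repulsive), radially enveloped
    t = np.tanh((r - params.site_cutoff_radius) / params.site_cutoff_width)
    env = 0.5 * (1.0 - t)
    denv = -0.5 * (1.0 - t * t) / params.site_cutoff_width  # d env / d r
    for (cx, cy), d, sw in zip(params.site_xy, params.site_depth_array,
                               params.site_width_array):
        ddx, ddy = x - cx, y - cy
        g = np.exp(-(ddx * ddx + ddy * ddy) / (2.0 * sw ** 2))
        w = (d / sw ** 2) * env * g
        fx = fx - w * ddx
        fy = fy - w * ddy
        # envelope gradient: -d/dx [-d g env] radial part
        rad = d * g * denv
        fx = fx + rad * x * inv_r
        fy = fy + rad * y * inv_r

    # confining wall
    over = np.maximum(r - params.wall_radius, 0.0)
    wallmag = 4.0 * params.wall_strength * over ** 3
    fx = fx - wallmag * x * inv_r
    fy = fy - wallmag * y * inv_r
    return np.stack([fx, fy], axis=-1)


def _calibrate_barrier(params: SurrogateParams) -> float:
    """Solve for the barrier-ring amplitude realizing ``barrier_height``.

    Measured along the ray through the deepest site (the lowest crossing of
    the ring): realized barrier = max U between the product and ion-pair
    minima, minus the ion-pair minimum.
    """
    depths = params.site_depth_array
    theta0 = params.site_angles[int(np.argmax(depths))]
    rgrid = np.arange(0.02, R_ION_PAIR_OUTER + 0.5, 0.002)
    x, y = rgrid * math.cos(theta0), rgrid * math.sin(theta0)

    def realized(amp: float) -> float:
        u = _landscape_xy(params, x, y, barrier_amplitude=amp)
        ip_band = (rgrid >= R_ION_PAIR_INNER) & (rgrid <= R_ION_PAIR_OUTER)
        i_ip = np.flatnonzero(ip_band)[np.argmin(u[ip_band])]
        i_prod = int(np.argmin(u[rgrid < params.r_product]))
        saddle = float(np.max(u[i_prod:i_ip + 1]))
        return saddle - float(u[i_ip])

    target = params.barrier_height
    lo, hi = 0.0, target + 5.0
    while realized(hi) < target:
        hi *= 2.0
        if hi > 1e4:
            raise ValueError("cannot realize requested barrier height")
    if realized(lo) >= target:
        return 0.0
    return float(optimize.brentq(
        lambda a: realized(a) - target, lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# Presets

_PRESETS: dict[str, dict] = {
    # Barrier heights are set so the transition-ring crossing sits well above
    # the unassociated baseline (activation control: most collisions bounce
    # back), ordered OCH3 > H > CF3 by ~1.3-1.5 kT steps.
    #
    # Electron-donating substituent: highest activation barrier, deepest
    # peripheral wells (pronounced propeller crawling), five-letter alphabet.
    "OCH3": dict(
        barrier_height=7.0,
        site_labels=("O", "P", "O", "P", "X", "S"),
        site_well_depth=(("O", 2.2), ("P", 2.2), ("X", 2.2), ("S", 2.2)),
        # wide wells overlap into a ring channel: easy inter-site crawling;
        # the earlier cutoff keeps their broad tails out of the collision
        # shell (every preset's landscape is neutral beyond ~4.6)
        site_well_width=(("O", 0.75), ("P", 0.75), ("X", 0.75), ("S", 0.75)),
        site_cutoff_radius=4.35,
    ),
    # Unsubstituted cation: intermediate barrier, three-letter alphabet.
    "H": dict(
        barrier_height=4.9,
        site_labels=("O", "P", "O", "P", "O", "P"),
        site_well_depth=(("O", 1.6), ("P", 1.6)),
    ),
    # Electron-withdrawing substituent: lowest barrier, and a disfavoured
    # substituted ring: repulsive patches at the X/S carbons keep the anion
    # dwelling at the O/P sites of the unsubstituted rings, concentrating
    # contacts there (and no addition at S).
    "CF3": dict(
        barrier_height=3.3,
        site_labels=("O", "P", "O", "P", "X", "S"),
        site_well_depth=(("O", 1.2), ("P", 1.2), ("X", -1.5), ("S", -1.5)),
        site_well_width=(("X", 1.2), ("S", 1.2)),
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def make_surrogate(preset: "str | SurrogateParams" = "H", **overrides) -> SurrogateParams:
    """Build surrogate parameters from a named preset or explicit parameters.

    Presets encode the substituent series: identical long-range attraction
    (the diffusional-encounter step is substituent-independent) but
    activation barriers ordered OCH3 > H > CF3.
    """
    if isinstance(preset, SurrogateParams):
        return replace(preset, **overrides) if overrides else preset
    try:
        kwargs = dict(_PRESETS[preset])
    except KeyError:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESET_NAMES}") from None
    kwargs.update(overrides)
    return SurrogateParams(**kwargs)


# ---------------------------------------------------------------------------
# Energies and dynamics

def potential(params: SurrogateParams, config: Configuration) -> float:
    """Potential energy (kT) of a single configuration."""
    x, y = config.xy
    return float(_landscape_xy(params, x, y))


def potential_xy(params: SurrogateParams, x, y) -> np.ndarray:
    """Vectorized potential energy (kT) on Cartesian arrays."""
    return _landscape_xy(params, x, y)


def propagate_batch(params: SurrogateParams, xy: np.ndarray, n_steps: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Overdamped Euler--Maruyama update of a batch of walkers.

    x <- x + (dt/gamma) F(x) + sqrt(2 kT dt / gamma) xi,  xi ~ N(0, 1).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    xy = np.array(xy, dtype=float, copy=True)
    drift = params.dt / params.gamma
    sigma = math.sqrt(2.0 * params.kT * params.dt / params.gamma)
    for _ in range(n_steps):
        f = force_xy(params, xy)
        if not np.all(np.isfinite(f)):
            raise FloatingPointError("non-finite force; malformed surrogate parameters")
        xy += drift * f
        if sigma > 0.0:
            xy += sigma * rng.standard_normal(xy.shape)
    return xy


def propagate(params: SurrogateParams, config: Configuration, n_steps: int,
              seed: "int | np.random.Generator") -> Configuration:
    """Propagate a single configuration; bit-reproducible for a given seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = propagate_batch(params, config.xy[None, :], n_steps, rng)[0]
    return Configuration.from_xy(out[0], out[1])


def product_minimum(params: SurrogateParams) -> Configuration:
    """Locate the product-well minimum (near, not exactly at, the origin)."""
    res = optimize.minimize(
        lambda p: float(_landscape_xy(params, p[0], p[1])),
        x0=np.zeros(2), method="BFGS",
        jac=lambda p: -force_xy(params, p[None, :])[0], tol=1e-14)
    return Configuration.from_xy(res.x[0], res.x[1])


# ---------------------------------------------------------------------------
# Discretization

def classify_r(r) -> np.ndarray:
    """Macrostate codes for radii: 0 unassociated, 1 ion pair, 2 product, -1 none."""
    r = np.asarray(r, dtype=float)
    codes = np.full(r.shape, -1, dtype=np.int64)
    codes[r > R_UNASSOCIATED] = 0
    codes[(r >= R_ION_PAIR_INNER) & (r <= R_ION_PAIR_OUTER)] = 1
    codes[r < R_PRODUCT] = 2
    return codes


def classify_macrostate(config: Configuration) -> str | None:
    """Macrostate label of a configuration, or None in buffer regions."""
    code = int(classify_r(config.r))
    return MACROSTATES[code] if code >= 0 else None


def site_labels_xy(params: SurrogateParams, xy: np.ndarray) -> np.ndarray:
    """Vectorized nearest-site labels for Cartesian points.

    The central carbon T competes as a site at the origin; any point inside
    the product radius maps to T regardless.  Ties go to the lowest site
    index (T first), which makes the discretization deterministic.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    centers = np.vstack([[0.0, 0.0], params.site_xy])
    labels = np.array(["T", *params.site_labels])
    d2 = ((xy[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)  # argmin takes the first minimum: lowest index
    out = labels[idx]
    out[np.hypot(xy[:, 0], xy[:, 1]) < params.r_product] = "T"
    return out


def nearest_site(params: SurrogateParams, config: Configuration) -> str:
    """Symmetry-adapted label of the site nearest to a configuration."""
    return str(site_labels_xy(params, config.xy[None, :])[0])


def initial_pool(params: SurrogateParams, n: int = 50, seed: int = 0,
                 r_init: float = 20.0) -> np.ndarray:
    """Unassociated starting ensemble: n points on the r = r_init ring.

    Emulates an equilibrated reactant ensemble with the anion--cation
    distance restrained to 20 and orientations randomized.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return r_init * np.stack([np.cos(theta), np.sin(theta)], axis=1)


# ---------------------------------------------------------------------------
# Parameter and fixture I/O

def params_to_dict(params: SurrogateParams) -> dict:
    """JSON/YAML-serializable form of surrogate parameters."""
    from dataclasses import asdict
    d = asdict(params)
    d["site_angles"] = list(d["site_angles"])
    d["site_labels"] = list(d["site_labels"])
    d["site_well_depth"] = {k: v for k, v in d["site_well_depth"]}
    d["site_well_width"] = {k: v for k, v in d["site_well_width"]}
    return d


def params_from_dict(d: dict) -> SurrogateParams:
    """Build parameters from a config block: either ``{"preset": name,
    <overrides...>}`` or a full explicit parameter mapping."""
    d = dict(d)
    preset = d.pop("preset", None)
    for key in ("site_angles", "site_labels"):
        if key in d:
            d[key] = tuple(d[key])
    for key in ("site_well_depth", "site_well_width"):
        if key in d and isinstance(d[key], dict):
            d[key] = tuple(d[key].items())
    if preset is not None:
        return make_surrogate(preset, **d)
    return SurrogateParams(**d)


def load_params(path: str) -> SurrogateParams:
    """Read surrogate parameters from a YAML config block."""
    import yaml
    with open(path) as f:
        return params_from_dict(yaml.safe_load(f) or {})


def write_label_sequences(path: str, sequences: list[str],
                          weights=None) -> None:
    """Plain-text fixture: one sequence per line, comma-separated weight."""
    if weights is None:
        weights = [1.0] * len(sequences)
    with open(path, "w") as f:
        for s, w in zip(sequences, weights):
            f.write(f"{s},{float(w)!r}\n")


def read_label_sequences(path: str) -> tuple[list[str], np.ndarray]:
    seqs, weights = [], []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line:
                continue
            s, _, w = line.partition(",")
            seqs.append(s)
            weights.append(float(w) if w else 1.0)
    return seqs, np.asarray(weights)


# ---------------------------------------------------------------------------
# Label-sequence fixtures for clustering

def generate_label_sequences(class_motifs: list[str], n_per_class: int,
                             mutation_rate: float, length_jitter: int,
                             seed: int, alphabet: "str | None" = None
                             ) -> tuple[list[str], np.ndarray]:
    """Planted-class site-label sequences with known ground truth.

    Each sequence is its class motif subjected to up to ``length_jitter``
    random single-position duplications or deletions followed by per-position
    substitutions at ``mutation_rate``.  Returns (sequences, true class ids).
    """
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must lie in [0, 1]")
    if len(set(class_motifs)) != len(class_motifs):
        raise ValueError("class motifs must be pairwise distinct")
    rng = np.random.default_rng(seed)
    letters = sorted(set(alphabet or "".join(class_motifs)))
    seqs: list[str] = []
    truth: list[int] = []
    for cid, motif in enumerate(class_motifs):
        for _ in range(n_per_class):
            chars = list(motif)
            if length_jitter > 0:
                shift = int(rng.integers(-length_jitter, length_jitter + 1))
                for _ in range(abs(shift)):
                    pos = int(rng.integers(0, len(chars)))
                    if shift > 0:
                        chars.insert(pos, chars[pos])  # duplicate a position
                    elif len(chars) > 1:
                        del chars[pos]
            for i in range(len(chars)):
                if rng.random() < mutation_rate:
                    options = [c for c in letters if c != chars[i]] or letters
                    chars[i] = options[int(rng.integers(0, len(options)))]
            seqs.append("".join(chars))
            truth.append(cid)
    return seqs, np.asarray(truth)
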