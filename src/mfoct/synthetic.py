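"""Synthetic ground-truth generators: canonical fractals, OCT-like retinal
phantoms, and statistical feature tables.

Every generator carries its own analytic oracle so that the estimation
pipeline can be validated without external data:

* filled rectangle — plane-filling set, D_q = 2 for all q;
* Sierpinski carpet — self-similar, D_q = log 8 / log 3 for all q,
  foreground count exactly 8^level;
* 2D binomial multiplicative cascade — product of two independent dyadic
  (p, 1-p) cascades, one per axis, giving the closed form
  D_q = 2 log2(p^q + (1-p)^q) / (1 - q) (entropy form at q = 1);
* random quadrant dust — at each halving step a random quadrant of every
  occupied cell is deleted, keeping k of 4, so D_0 = log2(k);
* two-class retinal phantom — layered OCT-like grayscale image whose DR
  variant carries cascade-clustered debris, texture disruption and
  lesion-like blobs, widening the measured singularity spectrum;
* Gaussian feature-table sampler calibrated against published global
  summary statistics of the nine descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .multifractal import FEATURE_NAMES

__all__ = [
    "FractalSpec",
    "PhantomSpec",
    "FeatureDistribution",
    "make_filled_rect",
    "make_sierpinski_carpet",
    "make_binomial_cascade",
    "make_random_dust",
    "make_fractal",
    "make_retina_phantom",
    "phantom_feature_table",
    "sample_feature_table",
    "binarize_mass_map",
    "carpet_dimension",
    "cascade_generalized_dimension",
    "cascade_holder_exponent",
    "cascade_spectrum_width",
    "DEFAULT_SEED",
]

#: fallback seed for library calls that omit one (mirrors the classifier default)
DEFAULT_SEED = 42

FRACTAL_KINDS = ("filled_rect", "sierpinski_carpet", "binomial_cascade", "random_dust")


@dataclass(frozen=True)
class FractalSpec:
    """Recipe for one canonical fractal image."""

    kind: str
    level: int = 5
    p: float = 0.7  # cascade weight, only used for binomial_cascade
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in FRACTAL_KINDS:
            raise ValueError(f"unknown fractal kind {self.kind!r}")
        if self.level < 1:
            raise ValueError(f"level must be >= 1, got {self.level}")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one OCT-like retinal phantom.

    ``cascade_heterogeneity`` in [0, 1] controls the multifractal texture
    disruption (debris density and bright-layer modulation); the DR default
    exceeds the Normal default so that the expected singularity-spectrum
    width is larger for DR.  ``None`` fields take the class default.
    """

    class_label: str = "DR"
    image_side: int = 256
    n_layers: int = 7
    cascade_heterogeneity: float | None = None
    lesion_count: int | None = None
    noise_sd: float = 8.0
    seed: int = DEFAULT_SEED

    #: class defaults, DR deliberately more heterogeneous than Normal
    _HET_DEFAULTS = {"DR": 0.65, "Normal": 0.05}
    _LESION_DEFAULTS = {"DR": 6, "Normal": 0}

    def __post_init__(self) -> None:
        if self.class_label not in ("DR", "Normal"):
            raise ValueError(f"class_label must be 'DR' or 'Normal', got {self.class_label!r}")
        if self.image_side < 128:
            raise ValueError(f"image_side must be >= 128, got {self.image_side}")
        if self.n_layers < 2:
            raise ValueError(f"n_layers must be >= 2, got {self.n_layers}")
        het = self.heterogeneity
        if not 0.0 <= het <= 1.0:
            raise ValueError(f"cascade_heterogeneity must lie in [0, 1], got {het}")
        if self.lesions < 0:
            raise ValueError("lesion_count must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def heterogeneity(self) -> float:
        if self.cascade_heterogeneity is None:
            return self._HET_DEFAULTS[self.class_label]
        return self.cascade_heterogeneity

    @property
    def lesions(self) -> int:
        if self.lesion_count is None:
            return self._LESION_DEFAULTS[self.class_label]
        return self.lesion_count


# --- canonical fractals ---------------------------------------------------


def make_filled_rect(side: int) -> np.ndarray:
    """All-foreground square mask: the plane-filling monofractal, D_q = 2."""
    if side < 8:
        raise ValueError(f"side must be >= 8, got {side}")
    return np.ones((side, side), dtype=bool)


def make_sierpinski_carpet(level: int) -> np.ndarray:
    """Sierpinski carpet of the given recursion depth (side 3^level).

    Deterministic; foreground count is exactly 8^level and the similarity
    dimension is log 8 / log 3 ~ 1.8928.
    """
    if not 1 <= level <= 7:
        raise ValueError(f"level must be in [1, 7], got {level}")
    mask = np.ones((1, 1), dtype=bool)
    for _ in range(level):
        n = mask.shape[0]
        out = np.zeros((3 * n, 3 * n), dtype=bool)
        for i in range(3):
            for j in range(3):
                if i == 1 and j == 1:
                    continue
                out[i * n : (i + 1) * n, j * n : (j + 1) * n] = mask
        mask = out
    return mask


def make_binomial_cascade(level: int, p: float, seed: int | None = None) -> np.ndarray:
    """2D binomial multiplicative cascade mass map of side 2^level.

    Construction: starting from unit mass on one cell, every cell is split
    into 2x2 children whose weights are the outer product of an independent
    row split and column split, each (p, 1-p) in seeded random orientation.
    The result is the product measure of two 1D dyadic binomial cascades,
    hence D_q = 2 log2(p^q + (1-p)^q)/(1-q) (see
    :func:`cascade_generalized_dimension`).  Total mass is conserved to
    1e-9 at every level.
    """
    if not 1 <= level <= 11:
        raise ValueError(f"level must be in [1, 11], got {level}")
    if not 0.5 < p < 1.0:
        raise ValueError(f"cascade weight p must lie strictly in (0.5, 1.0), got {p}")
    rng = np.random.default_rng(DEFAULT_SEED if seed is None else seed)
    mass = np.ones((1, 1))
    for _ in range(level):
        n = mass.shape[0]
        wr = np.where(rng.integers(0, 2, size=(n, n)) == 0, p, 1.0 - p)
        wc = np.where(rng.integers(0, 2, size=(n, n)) == 0, p, 1.0 - p)
        out = np.empty((2 * n, 2 * n))
        out[0::2, 0::2] = mass * wr * wc
        out[0::2, 1::2] = mass * wr * (1.0 - wc)
        out[1::2, 0::2] = mass * (1.0 - wr) * wc
        out[1::2, 1::2] = mass * (1.0 - wr) * (1.0 - wc)
        mass = out
    return mass


def make_random_dust(level: int, keep: int = 3, seed: int | None = None) -> np.ndarray:
    """Random quadrant dust of side 2^level keeping ``keep`` of 4 children.

    Every occupied cell is subdivided into 2x2 and ``4 - keep`` random
    children are deleted, so the similarity dimension is log2(keep).
    """
    if not 1 <= level <= 11:
        raise ValueError(f"level must be in [1, 11], got {level}")
    if not 1 <= keep <= 4:
        raise ValueError(f"keep must be in [1, 4], got {keep}")
    rng = np.random.default_rng(DEFAULT_SEED if seed is None else seed)
    mask = np.ones((1, 1), dtype=bool)
    for _ in range(level):
        n = mask.shape[0]
        out = np.zeros((2 * n, 2 * n), dtype=bool)
        # per parent cell, a random permutation of the 4 quadrants; keep the first `keep`
        order = rng.permuted(np.tile(np.arange(4), (n, n, 1)), axis=2)
        keep_q = order[:, :, :keep]
        for qi, (di, dj) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
            sel = mask & np.any(keep_q == qi, axis=2)
            out[di::2, dj::2] = sel
        mask = out
    return mask


def make_fractal(spec: FractalSpec) -> np.ndarray:
    """Dispatch a :class:`FractalSpec` to its generator."""
    if spec.kind == "filled_rect":
        return make_filled_rect(2**spec.level if spec.level >= 3 else 8)
    if spec.kind == "sierpinski_carpet":
        return make_sierpinski_carpet(spec.level)
    if spec.kind == "binomial_cascade":
        return make_binomial_cascade(spec.level, spec.p, spec.seed)
    return make_random_dust(spec.level, seed=spec.seed)


def binarize_mass_map(mass: np.ndarray) -> np.ndarray:
    """Median threshold of a mass map (foreground strictly above the median).

    Keeps the foreground fraction near one half at every cascade level, so
    the binary view of a cascade is scale-free by construction.
    """
    mass = np.asarray(mass, dtype=float)
    return mass > np.median(mass)


# --- closed forms ---------------------------------------------------------


def carpet_dimension() -> float:
    """Similarity dimension of the Sierpinski carpet, log 8 / log 3."""
    return float(np.log(8.0) / np.log(3.0))


def cascade_generalized_dimension(q, p: float):
    """Closed-form D_q of the 2D product binomial cascade.

    D_q = 2 log2(p^q + (1-p)^q) / (1 - q) for q != 1 and twice the binary
    entropy of p at q = 1 (the product measure doubles the 1D exponents).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie in (0, 1), got {p}")
    q = np.asarray(q, dtype=float)
    c = 1.0 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 2.0 * np.log2(p**q + c**q) / (1.0 - q)
    d1 = 2.0 * (-(p * np.log2(p) + c * np.log2(c)))
    d = np.where(q == 1.0, d1, d)
    return float(d) if d.ndim == 0 else d


def cascade_holder_exponent(q, p: float):
    """Closed-form alpha(q) = d tau / d q of the 2D product binomial cascade."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie in (0, 1), got {p}")
    q = np.asarray(q, dtype=float)
    c = 1.0 - p
    num = p**q * np.log(p) + c**q * np.log(c)
    den = (p**q + c**q) * np.log(2.0)
    a = -2.0 * num / den
    return float(a) if a.ndim == 0 else a


def cascade_spectrum_width(p: float, q_min: float = -5.0, q_max: float = 5.0) -> float:
    """Closed-form spectrum width alpha(q_min) - alpha(q_max) on a finite q range."""
    return float(cascade_holder_exponent(q_min, p) - cascade_holder_exponent(q_max, p))


# --- retinal phantoms -----------------------------------------------------


def _cascade_field(rng: np.random.Generator, side: int, p: float, level: int) -> np.ndarray:
    """Cascade mass map upsampled/cropped to ``side`` x ``side``."""
    mass = make_binomial_cascade(level, p, seed=int(rng.integers(2**31)))
    n = mass.shape[0]
    if n < side:
        factor = -(-side // n)
        mass = np.kron(mass, np.ones((factor, factor)))
    return mass[:side, :side]


def make_retina_phantom(spec: PhantomSpec) -> np.ndarray:
    """Layered OCT-like grayscale phantom (8-bit), reproducible given the seed.

    The Normal variant is a clean stack of alternating bright/dark
    horizontal bands with additive speckle noise.  Heterogeneity adds, in
    proportion to ``cascade_heterogeneity``: multiplicative cascade
    modulation of the bright layers (texture disruption) and small bright
    debris specks in the dark regions whose positions are drawn from a
    cascade measure (clustered hyper-reflective foci).  Lesion-like dark
    blobs are stamped last.  The debris specks dominate the sparse tail of
    the box measure after preprocessing, so the DR defaults widen the
    measured singularity spectrum.
    """
    side = spec.image_side
    het = spec.heterogeneity
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:side, 0:side]

    n_layers = spec.n_layers
    edges = np.linspace(0.08, 0.92, n_layers + 1) * side
    edges[1:-1] += rng.normal(0.0, side * 0.008, n_layers - 1)
    intens = np.empty(n_layers)
    intens[::2] = rng.uniform(185, 220, intens[::2].size)
    intens[1::2] = rng.uniform(32, 50, intens[1::2].size)
    base = np.full((side, side), 25.0)
    for k in range(n_layers):
        base = np.where((yy >= edges[k]) & (yy < edges[k + 1]), intens[k], base)
    dark = base < 100

    p_cas = 0.5 + 0.3 * het
    if het > 0:
        # texture disruption of the bright layers (smoothed fine cascade)
        fine_level = max(1, int(np.ceil(np.log2(side))))
        texture = _cascade_field(rng, side, p_cas, fine_level)
        texture = ndimage.gaussian_filter(texture / texture.mean(), 2.0)
        modulation = np.clip(1.0 + 0.8 * het * (texture - 1.0), 0.15, 1.8)
        base = np.where(~dark, base * modulation, base)

    # debris specks in dark regions, positions weighted by a coarse cascade
    # (truncation keeps near-homogeneous phantoms speck-free)
    n_speck = int(60 * het**1.5)
    if n_speck:
        coarse = _cascade_field(rng, side, p_cas, 6)
        ys, xs = np.where(dark)
        weights = coarse[ys, xs]
        weights = weights / weights.sum()
        picks = rng.choice(ys.size, size=n_speck, p=weights)
        for i in picks:
            r = rng.uniform(2.0, 3.0)
            base[(yy - ys[i]) ** 2 + (xx - xs[i]) ** 2 < r**2] = 235.0

    # lesion-like dark blobs (fluid pockets) in the layered band
    for _ in range(spec.lesions):
        cy = rng.uniform(0.2, 0.8) * side
        cx = rng.uniform(0.1, 0.9) * side
        ry = rng.uniform(5, 14)
        rx = rng.uniform(8, 22)
        base[((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 < 1.0] = 15.0

    img = base + rng.normal(0.0, spec.noise_sd, base.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def phantom_feature_table(
    n_per_class: int,
    seed: int = DEFAULT_SEED,
    image_side: int = 256,
    preprocess_config=None,
    boxcount_config=None,
):
    """End-to-end synthetic study table: phantoms -> preprocessing -> descriptors.

    Generates ``n_per_class`` DR and Normal phantoms (per-image seeds drawn
    from ``seed``), runs the standard preprocessing chain and the
    box-counting extraction, and returns the labelled feature table
    (pandas DataFrame with the canonical columns).
    """
    import pandas as pd

    from .multifractal import MultifractalModel
    from .preprocess import preprocess_image

    rng = np.random.default_rng(seed)
    rows = []
    next_id = 1
    for label in ("DR", "Normal"):
        for _ in range(n_per_class):
            spec = PhantomSpec(
                class_label=label,
                image_side=image_side,
                seed=int(rng.integers(2**31)),
            )
            mask = preprocess_image(make_retina_phantom(spec), preprocess_config)
            feats = MultifractalModel(mask, config=boxcount_config).fit().features
            rows.append({"ID": next_id, **feats.as_dict(), "class": label})
            next_id += 1
    return pd.DataFrame(rows, columns=["ID", *FEATURE_NAMES, "class"])


# --- statistical feature tables ------------------------------------------

# global summary moments of the nine descriptors (mean, sd) that the merged
# two-class sampler reproduces, plus the DR-minus-Normal mean offsets used
# to inject a qualitatively realistic class difference (wider spectra,
# higher alpha_max/alpha_center and more negative shift for DR).
_GLOBAL_MOMENTS = {
    #                 mean      sd      DR - Normal
    "Db":             (1.9990, 0.0022,  0.00),
    "Di":             (1.9419, 0.0233,  0.02),
    "Dc":             (1.8925, 0.0402,  0.04),
    "alpha_min":      (1.7404, 0.0528,  0.00),
    "alpha_max":      (2.8345, 0.2417,  0.35),
    "alpha_center":   (2.2874, 0.1380,  0.18),
    "f_alpha_max":    (1.9990, 0.0022,  0.00),
    "spectrum_width": (1.0941, 0.2150,  0.30),
    "symmetric_shift": (-0.2312, 0.1540, -0.20),
}


@dataclass
class FeatureDistribution:
    """Class-conditional Gaussian model of the nine descriptors.

    ``means``/``sds`` map class label -> array of 9 per-descriptor moments.
    The default (:meth:`table_defaults`) places the two class means
    symmetrically about the published global mean and shrinks the
    within-class sd so that the equal-weight merge of the two classes
    reproduces the global mean and sd of every column exactly (in
    expectation).  ``f_alpha_max`` duplicates ``Db`` row-wise, as in the
    extraction pipeline.  An optional correlation matrix (9x9, applied to
    both classes) can impose covariance structure.
    """

    means: dict[str, np.ndarray]
    sds: dict[str, np.ndarray]
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        for label in ("DR", "Normal"):
            if label not in self.means or label not in self.sds:
                raise ValueError(f"missing moments for class {label!r}")
            self.means[label] = np.asarray(self.means[label], dtype=float)
            self.sds[label] = np.asarray(self.sds[label], dtype=float)
            if self.means[label].shape != (9,) or self.sds[label].shape != (9,):
                raise ValueError("per-class moments must have 9 entries")
            if np.any(self.sds[label] < 0):
                raise ValueError("standard deviations must be >= 0")
        if self.correlation is not None:
            self.correlation = np.asarray(self.correlation, dtype=float)
            if self.correlation.shape != (9, 9):
                raise ValueError("correlation must be 9x9")

    @classmethod
    def table_defaults(cls) -> "FeatureDistribution":
        means = {"DR": [], "Normal": []}
        sds = {"DR": [], "Normal": []}
        for name in FEATURE_NAMES:
            mean, sd, delta = _GLOBAL_MOMENTS[name]
            if abs(delta) > 2 * sd:
                raise ValueError(f"class offset for {name} exceeds the global spread")
            within = float(np.sqrt(sd**2 - 0.25 * delta**2))
            means["DR"].append(mean + delta / 2.0)
            means["Normal"].append(mean - delta / 2.0)
            sds["DR"].append(within)
            sds["Normal"].append(within)
        return cls(means=means, sds=sds)


def sample_feature_table(
    dist: FeatureDistribution | None = None,
    n_per_class: int = 100,
    seed: int = DEFAULT_SEED,
):
    """Draw a balanced labelled feature table (pandas DataFrame).

    Rows are 2 * ``n_per_class``; columns follow the canonical CSV header
    ``ID, Db, ..., symmetric_shift, class``.  ``f_alpha_max`` is set equal
    to ``Db`` row by row (the two columns are identical in the extraction
    pipeline).  Sampling is independent per descriptor unless the
    distribution carries a correlation matrix.
    """
    import pandas as pd

    if dist is None:
        dist = FeatureDistribution.table_defaults()
    if n_per_class < 2:
        raise ValueError(f"n_per_class must be >= 2, got {n_per_class}")
    rng = np.random.default_rng(seed)
    frames = []
    next_id = 1
    i_db = FEATURE_NAMES.index("Db")
    i_fm = FEATURE_NAMES.index("f_alpha_max")
    for label in ("DR", "Normal"):
        mu = dist.means[label]
        sd = dist.sds[label]
        z = rng.standard_normal((n_per_class, 9))
        if dist.correlation is not None:
            z = z @ np.linalg.cholesky(dist.correlation).T
        block = mu + z * sd
        block[:, i_fm] = block[:, i_db]
        frame = pd.DataFrame(block, columns=list(FEATURE_NAMES))
        frame.insert(0, "ID", np.arange(next_id, next_id + n_per_class))
        frame["class"] = label
        next_id += n_per_class
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
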