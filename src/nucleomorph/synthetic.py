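"""Synthetic fixtures: tiles with ground truth, training sets, and cohorts.

This module emulates the study conditions every downstream stage needs,
without any external data:

* grayscale histology-like tiles of elliptical nuclei, dark on a bright
  background (hematoxylin convention), with a planted label map;
* nucleus populations spanning the oligodendroglioma-astrocytoma morphology
  continuum (round/small vs elongated/large nuclei);
* training tables of nuclear features with "human" Nuclear Scores generated
  by a known linear model plus noise and optional gross outliers;
* multi-platform cohorts (per-patient nuclear features, expression matrix,
  survival, binary alteration flags) whose structure is driven by a planted
  per-patient oligodendroglioma mixing fraction pi.

All randomness flows through a single seeded :class:`numpy.random.Generator`;
identical seeds reproduce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nucleomorph.features import FEATURE_NAMES

__all__ = [
    "NucleusSpec",
    "SyntheticTile",
    "TrainingSet",
    "SyntheticCohort",
    "CLASS_PARAMS",
    "sample_population",
    "render_tile",
    "make_training_set",
    "make_cohort",
]

CLASSES = ("oligo", "astro", "intermediate")

#: Default morphology continuum parameterization (uniform ranges).  Oligo
#: nuclei are small and nearly circular; astro nuclei are larger and
#: elongated with coarser chromatin texture; intermediate interpolates.
CLASS_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "oligo": {
        "semi_major": (5.0, 8.0),
        "axis_ratio": (0.85, 1.0),
        "mean_intensity": (0.25, 0.35),
        "texture_sd": (0.01, 0.03),
    },
    "astro": {
        "semi_major": (9.0, 14.0),
        "axis_ratio": (0.30, 0.60),
        "mean_intensity": (0.30, 0.45),
        "texture_sd": (0.04, 0.08),
    },
    "intermediate": {
        "semi_major": (7.0, 11.0),
        "axis_ratio": (0.60, 0.85),
        "mean_intensity": (0.28, 0.40),
        "texture_sd": (0.02, 0.05),
    },
}

#: Nuclear Score range generated per class: oligo nuclei score low (classic
#: oligodendroglioma = 1), astro nuclei high (classic astrocytoma = 10).
CLASS_NS_RANGE = {"oligo": (1.0, 2.0), "intermediate": (3.0, 6.0), "astro": (6.5, 10.0)}


@dataclass(frozen=True)
class NucleusSpec:
    """Geometry and appearance of one synthetic nucleus."""

    center: tuple[float, float]  # (row, col), 0-based pixels
    semi_major: float  # pixels
    semi_minor: float  # pixels
    orientation: float  # radians, counter-clockwise from the column axis
    mean_intensity: float  # in (0, 1); nuclei are darker than background
    texture_sd: float  # in [0, 1]; chromatin texture roughness
    class_label: str  # one of CLASSES

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("require semi_major >= semi_minor > 0")
        if not (0.0 < self.mean_intensity < 1.0):
            raise ValueError("mean_intensity must lie in (0, 1)")
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class_label {self.class_label!r}")


@dataclass
class SyntheticTile:
    """A rendered tile, its ground-truth label map, and the retained specs."""

    image: np.ndarray  # float64 in [0, 1]
    truth: np.ndarray  # int32 label map, 0 = background
    specs: list[NucleusSpec]  # one per positive truth label, in label order


@dataclass
class TrainingSet:
    """Feature table with human-style Nuclear Scores from a known model."""

    features: pd.DataFrame
    scores: pd.Series  # clamped to [1, 10], name "human_ns"
    raw_scores: pd.Series  # pre-clamp linear scores (incl. outlier offsets)
    outlier_mask: np.ndarray  # True where a gross error was injected
    theta_true: np.ndarray  # intercept followed by one coefficient per column


@dataclass
class SyntheticCohort:
    """Multi-platform synthetic cohort with planted ground truth."""

    patients: pd.DataFrame  # patient_id, group, mixing_fraction, hoc
    nuclei: pd.DataFrame  # patient_id, class_label, ns_true + feature columns
    expression: pd.DataFrame  # genes x patients
    survival: pd.DataFrame  # patient_id, days, event, treatment
    alterations: pd.DataFrame  # patients x binary event flags
    signature_genes: list[str]
    truth: dict = field(default_factory=dict)  # planted parameters


def _uniform(rng: np.random.Generator, lohi: tuple[float, float], size=None):
    return rng.uniform(lohi[0], lohi[1], size=size)


def sample_population(
    n: int,
    class_mix: tuple[float, float, float],
    seed: int | np.random.Generator = 0,
    shape: tuple[int, int] = (512, 512),
    margin: float = 16.0,
    min_separation: float | None = None,
    class_params: dict | None = None,
) -> list[NucleusSpec]:
    """Sample ``n`` nucleus specs from the oligo/astro/intermediate mixture.

    ``class_mix`` gives probabilities over ``("oligo", "astro",
    "intermediate")`` and must sum to 1.  Centers are placed uniformly inside
    ``shape`` with a ``margin`` from the border; if ``min_separation`` is
    given, centers are rejection-sampled to be at least that far apart
    (controlled clumping for watershed tests).  ``n <= 0`` returns an empty
    list.
    """
    if n <= 0:
        return []
    mix = np.asarray(class_mix, dtype=float)
    if mix.shape != (3,) or not math.isclose(mix.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("class_mix must be 3 probabilities summing to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = class_params or CLASS_PARAMS

    labels = rng.choice(np.arange(3), size=n, p=mix)
    centers: list[tuple[float, float]] = []
    specs: list[NucleusSpec] = []
    max_tries = 200 * n + 1000
    tries = 0
    i = 0
    while i < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} centers with min_separation={min_separation} "
                f"in shape {shape}; placed {i}"
            )
        r = rng.uniform(margin, shape[0] - margin)
        c = rng.uniform(margin, shape[1] - margin)
        if min_separation is not None and any(
            (r - r0) ** 2 + (c - c0) ** 2 < min_separation**2 for r0, c0 in centers
        ):
            continue
        cls = CLASSES[labels[i]]
        p = params[cls]
        a = _uniform(rng, p["semi_major"])
        ratio = _uniform(rng, p["axis_ratio"])
        specs.append(
            NucleusSpec(
                center=(r, c),
                semi_major=a,
                semi_minor=max(a * ratio, 1e-6),
                orientation=rng.uniform(0.0, math.pi),
                mean_intensity=_uniform(rng, p["mean_intensity"]),
                texture_sd=_uniform(rng, p["texture_sd"]),
                class_label=cls,
            )
        )
        centers.append((r, c))
        i += 1
    return specs


def _ellipse_coverage(spec: NucleusSpec, shape: tuple[int, int]):
    """Pixel indices covered by the ellipse (center-in-ellipse test)."""
    r0, c0 = spec.center
    a, b = spec.semi_major, spec.semi_minor
    ext = a + 1.0
    rmin = max(int(math.floor(r0 - ext)), 0)
    rmax = min(int(math.ceil(r0 + ext)), shape[0] - 1)
    cmin = max(int(math.floor(c0 - ext)), 0)
    cmax = min(int(math.ceil(c0 + ext)), shape[1] - 1)
    if rmin > rmax or cmin > cmax:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    dr = rr - r0
    dc = cc - c0
    ct, st = math.cos(spec.orientation), math.sin(spec.orientation)
    u = dc * ct + dr * st
    v = -dc * st + dr * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return rr[inside], cc[inside]


def render_tile(
    specs: list[NucleusSpec],
    shape: tuple[int, int] = (512, 512),
    background_gradient: float = 0.05,
    noise_sd: float = 0.02,
    seed: int = 0,
    background_level: float = 0.85,
) -> SyntheticTile:
    """Render dark elliptical nuclei on a bright background with ground truth.

    The truth label map resolves overlapping ellipses by the nearest-center
    rule.  Specs that end up with no pixels (fully occluded or off-grid) are
    dropped and labels re-packed so that truth label ``k`` corresponds to
    ``specs[k-1]`` of the returned tile.

    Raises
    ------
    ValueError
        If any spec center lies outside ``shape`` (the spec index is named)
        or ``noise_sd < 0``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rows, cols = shape
    for i, s in enumerate(specs):
        r, c = s.center
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"spec {i} center {s.center} outside tile shape {shape}")

    rng = np.random.default_rng(seed)
    truth = np.zeros(shape, dtype=np.int32)
    # squared distance to the owning center, for nearest-center overlap resolution
    best = np.full(shape, np.inf)

    for i, s in enumerate(specs):
        rr, cc = _ellipse_coverage(s, shape)
        if rr.size == 0:
            continue
        d2 = (rr - s.center[0]) ** 2 + (cc - s.center[1]) ** 2
        closer = d2 < best[rr, cc]
        truth[rr[closer], cc[closer]] = i + 1
        best[rr[closer], cc[closer]] = d2[closer]

    # Drop occluded specs, re-pack labels contiguously.
    present = np.unique(truth)
    present = present[present > 0]
    retained = [specs[k - 1] for k in present]
    remap = np.zeros(len(specs) + 1, dtype=np.int32)
    remap[present] = np.arange(1, len(present) + 1, dtype=np.int32)
    truth = remap[truth]

    # Background: bright field with a linear ramp in a seeded direction.
    ang = rng.uniform(0, 2 * math.pi)
    rr, cc = np.mgrid[0:rows, 0:cols]
    ramp = rr * math.sin(ang) + cc * math.cos(ang)
    span = ramp.max() - ramp.min()
    if span > 0:
        ramp = (ramp - ramp.min()) / span
    image = background_level - background_gradient * ramp

    for k, s in enumerate(retained, start=1):
        pix = truth == k
        npx = int(pix.sum())
        image[pix] = s.mean_intensity + s.texture_sd * rng.standard_normal(npx)

    if noise_sd > 0:
        image = image + noise_sd * rng.standard_normal(shape)
    image = np.clip(image, 0.0, 1.0)
    return SyntheticTile(image=image, truth=truth, specs=retained)


def _spec_feature_row(rng: np.random.Generator, cls: str, params: dict) -> dict:
    """Parametric 23-feature vector for one nucleus of the given class.

    Morphometry follows from the sampled ellipse analytically (with mild
    measurement noise); intensity/texture/gradient features are drawn from
    class-dependent distributions so that the feature table carries the same
    oligo-astro structure a rendered-and-measured table would.
    """
    p = params[cls]
    a = _uniform(rng, p["semi_major"])
    ratio = _uniform(rng, p["axis_ratio"])
    b = a * ratio
    area = math.pi * a * b
    # Ramanujan ellipse perimeter approximation
    h = ((a - b) / (a + b)) ** 2
    perim = math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))
    ecc = math.sqrt(max(1 - ratio**2, 0.0))
    circ = 4 * math.pi * area / perim**2
    mean_int = _uniform(rng, p["mean_intensity"])
    tex = _uniform(rng, p["texture_sd"])
    jitter = lambda x, s: x * (1 + s * rng.standard_normal())  # noqa: E731
    std_int = tex + 0.005 * abs(rng.standard_normal())
    grad = 0.1 + 2.0 * tex + 0.02 * rng.standard_normal()
    return {
        "Area": jitter(area, 0.03),
        "Perimeter": jitter(perim, 0.02),
        "Eccentricity": float(np.clip(jitter(ecc, 0.03) if ecc > 0 else 0.01 * abs(rng.standard_normal()), 0, 0.999)),
        "Circularity": float(np.clip(jitter(circ, 0.02), 0.05, 1.0)),
        "MajorAxisLength": jitter(2 * a, 0.02),
        "MinorAxisLength": jitter(2 * b, 0.02),
        "Solidity": float(np.clip(0.97 - 0.1 * ecc + 0.01 * rng.standard_normal(), 0.5, 1.0)),
        "Extent": float(np.clip(0.78 - 0.1 * ecc + 0.02 * rng.standard_normal(), 0.2, 1.0)),
        "MeanIntensity": mean_int,
        "MaxIntensity": float(np.clip(mean_int + 2.5 * std_int, 0, 1)),
        "MinIntensity": float(np.clip(mean_int - 2.5 * std_int, 0, 1)),
        "StdIntensity": std_int,
        "Energy": float(np.clip(0.5 - 3.0 * tex + 0.02 * rng.standard_normal(), 0.01, 1.0)),
        "Entropy": float(np.clip(2.0 + 30.0 * tex + 0.1 * rng.standard_normal(), 0, 8)),
        "Skewness": 0.3 * rng.standard_normal(),
        "Kurtosis": 3.0 + 0.5 * rng.standard_normal(),
        "MeanGradMag": max(grad, 0.0),
        "StdGradMag": max(0.5 * grad + 0.01 * rng.standard_normal(), 0.0),
        "EntropyGradMag": float(np.clip(3.0 + 20.0 * tex + 0.1 * rng.standard_normal(), 0, 8)),
        "EnergyGradMag": float(np.clip(0.4 - 2.0 * tex + 0.02 * rng.standard_normal(), 0.01, 1.0)),
        "SkewnessGradMag": 0.5 + 0.3 * rng.standard_normal(),
        "KurtosisGradMag": 3.5 + 0.5 * rng.standard_normal(),
        "CannyPixelFraction": float(np.clip(0.05 + 0.8 * tex + 0.01 * rng.standard_normal(), 0, 1)),
    }


def make_training_set(
    n: int,
    theta_true,
    outlier_fraction: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    feature_names: list[str] | None = None,
    outlier_offset: float = 8.0,
) -> TrainingSet:
    """Generate a feature table and human-style NS column from a known model.

    ``theta_true`` is ``[intercept, coef_1, ..., coef_p]``; features are iid
    standard normal columns named after the first ``p`` canonical feature
    names (or ``feature_names``).  Scores are
    ``clamp(intercept + X @ coef + noise, 1, 10)``; a fraction
    ``outlier_fraction`` of rows receives a gross error of ``+-outlier_offset``
    before clamping (the affected rows are flagged).
    """
    if not (0.0 <= outlier_fraction < 0.5):
        raise ValueError("outlier_fraction must be in [0, 0.5)")
    theta = np.asarray(theta_true, dtype=float)
    p = theta.size - 1
    names = list(feature_names) if feature_names is not None else list(FEATURE_NAMES[:p])
    if len(names) != p:
        raise ValueError("feature_names length must match len(theta_true) - 1")
    rng = np.random.default_rng(seed)
    if n == 0:
        return TrainingSet(
            features=pd.DataFrame(columns=names, dtype=float),
            scores=pd.Series([], dtype=float, name="human_ns"),
            raw_scores=pd.Series([], dtype=float, name="raw_ns"),
            outlier_mask=np.zeros(0, dtype=bool),
            theta_true=theta,
        )
    X = rng.standard_normal((n, p))
    raw = theta[0] + X @ theta[1:]
    if noise_sd > 0:
        raw = raw + noise_sd * rng.standard_normal(n)
    n_out = round(n * outlier_fraction)
    mask = np.zeros(n, dtype=bool)
    if n_out > 0:
        idx = rng.choice(n, size=n_out, replace=False)
        mask[idx] = True
        raw = raw.copy()
        raw[idx] += outlier_offset * rng.choice([-1.0, 1.0], size=n_out)
    scores = np.clip(raw, 1.0, 10.0)
    feats = pd.DataFrame(X, columns=names)
    return TrainingSet(
        features=feats,
        scores=pd.Series(scores, name="human_ns"),
        raw_scores=pd.Series(raw, name="raw_ns"),
        outlier_mask=mask,
        theta_true=theta,
    )


def make_cohort(
    n_patients: int,
    group_sizes: tuple[int, int, int],
    effect_size: float = 1.5,
    seed: int = 0,
    nuclei_per_patient: int = 300,
    n_genes: int = 200,
    n_signature: int = 10,
    group_pi_means: tuple[float, float, float] = (0.15, 0.45, 0.80),
    group_pi_sd: float = 0.05,
    baseline_hazard: float = 1.0 / 400.0,
    treatment_log_hr: float = math.log(0.6),
    pi_log_hr: float = -0.5,
    censor_days: float = 1500.0,
    class_params: dict | None = None,
) -> SyntheticCohort:
    """Generate a cohort with planted low/medium/high oligodendroglioma groups.

    Each patient draws a mixing fraction ``pi`` from its planted group; the
    per-patient nucleus table mixes oligo (probability ``pi``) and astro
    nuclei with parametric features and a class-derived true Nuclear Score;
    signature-gene expression increases linearly in ``pi`` by ``effect_size``
    (all genes carry unit normal noise, so ``effect_size=0`` makes signature
    and background genes exchangeable); survival is exponential with a
    recorded treatment hazard ratio; alteration flags are Bernoulli with
    ``pi``-dependent rates.  All planted truths are returned in ``truth``.
    """
    gs = tuple(int(g) for g in group_sizes)
    if len(gs) != 3 or sum(gs) != n_patients or any(g < 0 for g in gs):
        raise ValueError("group_sizes must be 3 non-negative counts summing to n_patients")
    rng = np.random.default_rng(seed)
    params = class_params or CLASS_PARAMS

    pids = [f"P{i:04d}" for i in range(n_patients)]
    groups = np.repeat(np.arange(3), gs)
    pi = np.clip(
        np.asarray(group_pi_means)[groups] + group_pi_sd * rng.standard_normal(n_patients),
        0.02,
        0.98,
    )
    # Human OC grade: noisy discretization of pi.
    hoc = np.digitize(pi + 0.08 * rng.standard_normal(n_patients), [0.30, 0.65])

    patients = pd.DataFrame(
        {"patient_id": pids, "group": groups, "mixing_fraction": pi, "hoc": hoc}
    )

    nuc_rows = []
    for pid, p_oligo in zip(pids, pi):
        cls_draw = rng.random(nuclei_per_patient) < p_oligo
        for is_oligo in cls_draw:
            cls = "oligo" if is_oligo else "astro"
            row = _spec_feature_row(rng, cls, params)
            lo, hi = CLASS_NS_RANGE[cls]
            row["ns_true"] = rng.uniform(lo, hi)
            row["class_label"] = cls
            row["patient_id"] = pid
            nuc_rows.append(row)
    nuclei = pd.DataFrame(nuc_rows)
    nuclei = nuclei[["patient_id", "class_label", "ns_true", *FEATURE_NAMES]]

    sig = [f"SIG{i:03d}" for i in range(n_signature)]
    bg = [f"GENE{i:04d}" for i in range(n_genes - n_signature)]
    expr = rng.standard_normal((n_genes, n_patients))
    expr[:n_signature, :] += effect_size * pi[None, :]
    expression = pd.DataFrame(expr, index=sig + bg, columns=pids)

    treatment = (rng.random(n_patients) < 0.5).astype(int)
    lam = baseline_hazard * np.exp(treatment_log_hr * treatment + pi_log_hr * pi)
    t_event = rng.exponential(1.0 / lam)
    days = np.minimum(t_event, censor_days)
    event = (t_event <= censor_days).astype(int)
    survival = pd.DataFrame(
        {"patient_id": pids, "days": days, "event": event, "treatment": treatment}
    )

    alterations = pd.DataFrame(
        {
            "patient_id": pids,
            "AMP_A": (rng.random(n_patients) < 0.05 + 0.40 * pi).astype(int),
            "MUT_B": (rng.random(n_patients) < 0.45 - 0.30 * pi).astype(int),
            "MUT_C": (rng.random(n_patients) < 0.15).astype(int),
        }
    )

    return SyntheticCohort(
        patients=patients,
        nuclei=nuclei,
        expression=expression,
        survival=survival,
        alterations=alterations,
        signature_genes=sig,
        truth={
            "group_sizes": gs,
            "group_pi_means": tuple(group_pi_means),
            "effect_size": effect_size,
            "treatment_hr": math.exp(treatment_log_hr),
            "pi_log_hr": pi_log_hr,
            "baseline_hazard": baseline_hazard,
            "censor_days": censor_days,
            "seed": seed,
        },
    )


def tile_manifest(tile: SyntheticTile, seed: int, parameters: dict | None = None) -> dict:
    """JSON-serializable provenance record for a rendered tile."""
    return {
        "seed": seed,
        "shape": list(tile.image.shape),
        "n_nuclei": len(tile.specs),
        "parameters": parameters or {},
        "specs": [
            {**dataclasses.asdict(s), "center": list(s.center)} for s in tile.specs
        ],
    }
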