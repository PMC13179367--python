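"""Synthetic cohorts, single-cell panels, and multiplex IF images.

Every input the downstream stages consume can be generated here with known
ground truth: (i) patient cohorts with standardized indicators and a binary
response drawn from a logistic model with prescribed odds ratios per 1-SD;
(ii) per-cell metadata plus a negative-binomial expression panel with
group-specific fold changes planted in monocytes and power-law TCR
clonotype sizes; (iii) multi-channel fluorescence images (DAPI/CD14/CD16/
APOBEC3A) of non-overlapping elliptical nuclei with membrane-marker rings
and nuclear+ring APOBEC3A signal, with a per-cell phenotype ground truth.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import expit, logit

__all__ = [
    "CohortSimSpec",
    "CellSimSpec",
    "ImageSimSpec",
    "CohortData",
    "CellData",
    "ImageData",
    "gen_cohort",
    "gen_cells",
    "gen_image",
    "PHENOTYPE_MARKERS",
    "RESPONDER",
    "NONRESPONDER",
]

RESPONDER = "pCR/MPR"
NONRESPONDER = "NMPR"


# --------------------------------------------------------------------------
# patient cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimSpec:
    """Cohort generator settings.

    Indicators are standard normal marginally (z-score scale, so odds ratios
    are per 1-SD); the outcome follows
    logit{Pr(Y=1|X)} = alpha0 + sum_k ln(OR_k) X_k with alpha0 = logit(P).
    """

    n_patients: int = 54
    prevalence: float = 0.65
    or_per_sd: dict = field(default_factory=lambda: {"A": 2.3, "B": 2.3, "C": 2.3})
    indicator_correlation: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if not self.or_per_sd or any(v <= 0 for v in self.or_per_sd.values()):
            raise ValueError("all odds ratios must be > 0")
        if self.indicator_correlation is not None:
            corr = np.asarray(self.indicator_correlation, dtype=float)
            k = len(self.or_per_sd)
            if corr.shape != (k, k) or not np.allclose(corr, corr.T):
                raise ValueError("correlation matrix must be symmetric k x k")
            if np.linalg.eigvalsh(corr).min() < -1e-10:
                raise ValueError("correlation matrix must be positive semi-definite")


@dataclass
class CohortData:
    data: pd.DataFrame  # patient, indicator columns, y
    truth: dict  # alpha0 and log-odds per indicator


def gen_cohort(spec: CohortSimSpec) -> CohortData:
    """Draw an indicator matrix with logistic ground truth."""
    rng = np.random.default_rng(spec.seed)
    names = list(spec.or_per_sd)
    k = len(names)
    corr = (
        np.asarray(spec.indicator_correlation, dtype=float)
        if spec.indicator_correlation is not None
        else np.eye(k)
    )
    x = rng.multivariate_normal(np.zeros(k), corr, size=spec.n_patients)
    alpha0 = float(logit(spec.prevalence))
    sigmas = np.log([spec.or_per_sd[n] for n in names])
    p = expit(alpha0 + x @ sigmas)
    y = (rng.random(spec.n_patients) < p).astype(int)
    df = pd.DataFrame(x, columns=names)
    df.insert(0, "patient", [f"P{i + 1:03d}" for i in range(spec.n_patients)])
    df["y"] = y
    truth = {"alpha0": alpha0, "log_or": dict(zip(names, sigmas.tolist()))}
    return CohortData(data=df, truth=truth)


# --------------------------------------------------------------------------
# per-cell tables with expression panel
# --------------------------------------------------------------------------

_DEFAULT_PROPS = {
    RESPONDER: {"monocyte": 0.30, "T cell": 0.38, "B cell": 0.14,
                "NK cell": 0.10, "neutrophil": 0.08},
    NONRESPONDER: {"monocyte": 0.18, "T cell": 0.44, "B cell": 0.16,
                   "NK cell": 0.12, "neutrophil": 0.10},
}


@dataclass(frozen=True)
class CellSimSpec:
    """Single-cell generator settings.

    ``group_log2fc`` is applied to monocyte expression in the responder
    group; ``aberrant_samples`` maps a sample id to its own per-gene log2FC
    pattern (replacing the group effect in that sample's monocytes), used to
    plant influential samples for case-deletion diagnostics.
    """

    n_samples: dict = field(default_factory=lambda: {RESPONDER: 5, NONRESPONDER: 4})
    cells_per_sample: int = 300
    celltype_proportions: dict = field(default_factory=lambda: _DEFAULT_PROPS)
    panel: dict = field(default_factory=lambda: {"APOBEC3A": 2.0, "CD14": 5.0,
                                                 "FCGR3A": 3.0, "IFI6": 2.5})
    group_log2fc: dict = field(default_factory=dict)
    dispersion: float = 2.0
    clonotype_exponent: float = 2.0
    clonotype_max: int = 200
    aberrant_samples: dict = field(default_factory=dict)
    monocyte_type: str = "monocyte"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.panel:
            raise ValueError("panel must be non-empty")
        if self.cells_per_sample < 1:
            raise ValueError("cells_per_sample must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for g, props in self.celltype_proportions.items():
            total = sum(props.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"proportions for group {g!r} sum to {total}, not 1")


@dataclass
class CellData:
    cells: pd.DataFrame  # cell_id, sample, patient, group, cell_type, clonotype
    expr: sparse.csr_matrix  # cells x genes, raw counts
    genes: list[str]
    truth: dict


def _nb_counts(rng, mean, theta, size):
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p, size=size)


def _powerlaw_sizes(rng, n_cells, exponent, smax):
    s = np.arange(1, smax + 1, dtype=float)
    probs = s**-exponent
    probs /= probs.sum()
    sizes = []
    remaining = n_cells
    while remaining > 0:
        draw = int(rng.choice(s, p=probs))
        sizes.append(min(draw, remaining))
        remaining -= sizes[-1]
    return sizes


def gen_cells(spec: CellSimSpec) -> CellData:
    """Generate a per-cell table and sparse expression panel."""
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.panel)
    base = np.array([spec.panel[g] for g in genes], dtype=float)
    group_mult = np.array(
        [2.0 ** spec.group_log2fc.get(g, 0.0) for g in genes], dtype=float
    )
    rows, blocks = [], []
    sample_idx = 0
    for group, n_samp in spec.n_samples.items():
        props = spec.celltype_proportions[group]
        types = list(props)
        pvec = np.array([props[t] for t in types])
        for _ in range(n_samp):
            sample_idx += 1
            sample = f"P{sample_idx:02d}"
            counts = rng.multinomial(spec.cells_per_sample, pvec)
            cell_types = np.repeat(types, counts)
            rng.shuffle(cell_types)
            is_mono = cell_types == spec.monocyte_type
            mean = np.tile(base, (spec.cells_per_sample, 1))
            if sample in spec.aberrant_samples:
                mult = np.array(
                    [2.0 ** spec.aberrant_samples[sample].get(g, 0.0) for g in genes]
                )
                mean[is_mono] *= mult
            elif group == RESPONDER:
                mean[is_mono] *= group_mult
            blocks.append(_nb_counts(rng, mean, spec.dispersion, mean.shape))
            clono = np.full(spec.cells_per_sample, "", dtype=object)
            t_cells = np.flatnonzero(cell_types == "T cell")
            if t_cells.size:
                sizes = _powerlaw_sizes(rng, t_cells.size, spec.clonotype_exponent,
                                        spec.clonotype_max)
                ids = np.repeat(
                    [f"{sample}_C{j + 1}" for j in range(len(sizes))], sizes
                )
                clono[t_cells] = rng.permutation(ids)
            for i in range(spec.cells_per_sample):
                rows.append(
                    (f"{sample}_cell{i + 1}", sample, sample, group,
                     cell_types[i], clono[i])
                )
    cells = pd.DataFrame(
        rows, columns=["cell_id", "sample", "patient", "group", "cell_type", "clonotype"]
    )
    expr = sparse.csr_matrix(np.vstack(blocks))
    truth = {
        "group_log2fc": dict(spec.group_log2fc),
        "aberrant_samples": {k: dict(v) for k, v in spec.aberrant_samples.items()},
        "proportions": {g: dict(p) for g, p in spec.celltype_proportions.items()},
    }
    return CellData(cells=cells, expr=expr, genes=genes, truth=truth)


# --------------------------------------------------------------------------
# multiplex IF images
# --------------------------------------------------------------------------

#: Which markers each ground-truth phenotype carries.  Membrane markers
#: (CD14, CD16) are rendered as perinuclear rings; APOBEC3A as nucleus+ring.
PHENOTYPE_MARKERS = {
    "classical": {"CD14": True, "CD16": False, "APOBEC3A": False},
    "non_classical": {"CD14": False, "CD16": True, "APOBEC3A": False},
    "intermediate": {"CD14": True, "CD16": True, "APOBEC3A": False},
    "classical_a3a": {"CD14": True, "CD16": False, "APOBEC3A": True},
    "non_classical_a3a": {"CD14": False, "CD16": True, "APOBEC3A": True},
    "intermediate_a3a": {"CD14": True, "CD16": True, "APOBEC3A": True},
    "a3a_only": {"CD14": False, "CD16": False, "APOBEC3A": True},
    "negative": {"CD14": False, "CD16": False, "APOBEC3A": False},
}

_DEFAULT_MIX = {
    "classical": 0.18, "non_classical": 0.10, "intermediate": 0.08,
    "classical_a3a": 0.10, "non_classical_a3a": 0.07, "intermediate_a3a": 0.07,
    "a3a_only": 0.08, "negative": 0.32,
}

CHANNELS = ("DAPI", "CD14", "CD16", "APOBEC3A")


@dataclass(frozen=True)
class ImageSimSpec:
    """IF image generator settings (pixel units, 16-bit intensities)."""

    size: tuple[int, int] = (256, 256)
    n_cells: int = 25
    phenotype_mix: dict = field(default_factory=lambda: dict(_DEFAULT_MIX))
    radius_range: tuple[float, float] = (7.0, 10.0)
    max_eccentricity: float = 0.6
    ring_thickness: int = 3
    intensity: dict = field(
        default_factory=lambda: {c: (3000.0, 0.0) for c in CHANNELS}
    )
    noise_sd: float = 20.0
    background_amplitude: float = 10.0
    min_separation: float = 12.0
    max_attempts: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.ring_thickness < 1:
            raise ValueError("ring_thickness must be >= 1 px")
        total = sum(self.phenotype_mix.values())
        if self.phenotype_mix and not np.isclose(total, 1.0):
            raise ValueError(f"phenotype fractions sum to {total}, not 1")
        unknown = set(self.phenotype_mix) - set(PHENOTYPE_MARKERS)
        if unknown:
            raise ValueError(f"unknown phenotypes: {sorted(unknown)}")
        for c, (pos, neg) in self.intensity.items():
            if pos <= neg:
                raise ValueError(f"channel {c}: positive mean must exceed negative mean")
        if not 0 <= self.max_eccentricity < 1:
            raise ValueError("max_eccentricity must be in [0, 1)")


@dataclass
class ImageData:
    stack: np.ndarray  # (4, H, W) uint16, page order DAPI, CD14, CD16, APOBEC3A
    truth: pd.DataFrame  # one row per rendered nucleus
    n_requested: int
    n_placed: int


def _ellipse_masks(H, W, row, col, a, b, theta, ring):
    """Boolean nucleus and ring masks on the full grid (local computation)."""
    pad = int(np.ceil(a + ring + 2))
    r0, r1 = max(0, int(row) - pad), min(H, int(row) + pad + 1)
    c0, c1 = max(0, int(col) - pad), min(W, int(col) + pad + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr, dc = rr - row, cc - col
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    q = (u / a) ** 2 + (v / b) ** 2
    nucleus_loc = q <= 1.0
    # ring: within `ring` px of the ellipse, approximated by outward scaling
    qa = (u / (a + ring)) ** 2 + (v / (b + ring)) ** 2
    ring_loc = (qa <= 1.0) & ~nucleus_loc
    nucleus = np.zeros((H, W), dtype=bool)
    ringm = np.zeros((H, W), dtype=bool)
    nucleus[r0:r1, c0:c1] = nucleus_loc
    ringm[r0:r1, c0:c1] = ring_loc
    return nucleus, ringm


def gen_image(spec: ImageSimSpec) -> ImageData:
    """Render a multi-channel IF image with ground-truth phenotypes.

    Nuclei are ellipses (eccentricity capped so rings stay well-posed),
    placed by rejection sampling without overlap; a placement failure after
    ``max_attempts`` tries yields a partial image with a warning and a
    reduced cell count recorded in the result.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.size
    channels = {c: np.zeros((H, W), dtype=float) for c in CHANNELS}
    phenos = list(spec.phenotype_mix) or list(PHENOTYPE_MARKERS)
    mix = np.array([spec.phenotype_mix.get(p, 0.0) for p in phenos])
    if spec.n_cells and mix.sum() == 0:
        raise ValueError("phenotype mix is empty")
    placed = []  # (row, col, a)
    records = []
    rmin, rmax = spec.radius_range
    for j in range(spec.n_cells):
        phenotype = phenos[rng.choice(len(phenos), p=mix / mix.sum())] if mix.sum() else None
        a = rng.uniform(rmin, rmax)
        ecc = rng.uniform(0.0, spec.max_eccentricity)
        b = a * np.sqrt(1 - ecc**2)
        theta = rng.uniform(0, np.pi)
        margin = a + spec.ring_thickness + 6
        ok = False
        for _ in range(spec.max_attempts):
            row = rng.uniform(margin, H - margin)
            col = rng.uniform(margin, W - margin)
            if all(
                np.hypot(row - r2, col - c2) >= a + a2 + spec.min_separation
                for r2, c2, a2 in placed
            ):
                ok = True
                break
        if not ok:
            warnings.warn(
                f"placed only {len(placed)} of {spec.n_cells} nuclei "
                f"(rejection sampling exhausted)"
            )
            break
        placed.append((row, col, a))
        nucleus, ringm = _ellipse_masks(H, W, row, col, a, b, theta,
                                        spec.ring_thickness)
        markers = PHENOTYPE_MARKERS[phenotype]
        pos = {c: spec.intensity[c][0] for c in CHANNELS}
        channels["DAPI"][nucleus] = pos["DAPI"]
        if markers["CD14"]:
            channels["CD14"][ringm] = pos["CD14"]
        if markers["CD16"]:
            channels["CD16"][ringm] = pos["CD16"]
        if markers["APOBEC3A"]:
            channels["APOBEC3A"][nucleus | ringm] = pos["APOBEC3A"]
        records.append(
            {
                "cell_id": j + 1, "row": row, "col": col, "semi_major": a,
                "semi_minor": b, "orientation": theta, "phenotype": phenotype,
                "cd14": markers["CD14"], "cd16": markers["CD16"],
                "apobec3a": markers["APOBEC3A"],
            }
        )
    grad_r = np.linspace(0, 1, H)[:, None]
    grad_c = np.linspace(0, 1, W)[None, :]
    background = spec.background_amplitude * (grad_r + grad_c) / 2.0
    stack = np.empty((len(CHANNELS), H, W), dtype=np.uint16)
    for i, c in enumerate(CHANNELS):
        img = channels[c] + spec.intensity[c][1] + background
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        stack[i] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    truth = pd.DataFrame(
        records,
        columns=["cell_id", "row", "col", "semi_major", "semi_minor",
                 "orientation", "phenotype", "cd14", "cd16", "apobec3a"],
    )
    return ImageData(stack=stack, truth=truth, n_requested=spec.n_cells,
                     n_placed=len(records))
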