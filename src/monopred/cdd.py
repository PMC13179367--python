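"""Imitating case-deletion diagnostics (CDD) on single-cell DEG profiles.

Influential samples are detected by leave-one-out perturbation of the
group-versus-group differential-expression signature: DEGs (two-sided
rank-sum per gene, Bonferroni-adjusted, log2 fold change of pseudocount-
stabilized group means) are recomputed with one sample removed each time,
the per-deletion fold-change profiles are embedded by PCA, and a profile
whose robust distance from the medoid exceeds the cutoff flags its deleted
sample as a candidate outlier.  For each flagged sample, the top-k
upregulated and top-k downregulated DEG lists with (Control) and without
(Test) the sample are compared; the sample is retained when the lists stay
similar and removed otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .composition import rank_sum_p
from .synthdata import NONRESPONDER, RESPONDER

__all__ = [
    "compute_degs",
    "loo_profiles",
    "pca_outliers",
    "overlap_check",
    "OverlapResult",
    "run_cdd",
    "CaseDeletionDiagnostics",
    "CDDResults",
]

PSEUDOCOUNT = 1e-9


def _as_dense(expr) -> np.ndarray:
    if sparse.issparse(expr):
        return np.asarray(expr.todense(), dtype=float)
    return np.asarray(expr, dtype=float)


def _align(a, b, genes_a, genes_b):
    """Align two cells-x-genes matrices on the union panel, absent genes = 0."""
    if genes_a == genes_b:
        return _as_dense(a), _as_dense(b), list(genes_a)
    panel = sorted(set(genes_a) | set(genes_b))
    out = []
    for m, genes in ((a, genes_a), (b, genes_b)):
        m = _as_dense(m)
        full = np.zeros((m.shape[0], len(panel)))
        idx = {g: i for i, g in enumerate(panel)}
        for j, g in enumerate(genes):
            full[:, idx[g]] = m[:, j]
        out.append(full)
    return out[0], out[1], panel


def compute_degs(
    expr_a,
    expr_b,
    genes: list[str],
    genes_b: list[str] | None = None,
    pseudocount: float = PSEUDOCOUNT,
    exact_limit: int = 14,
) -> pd.DataFrame:
    """Two-group differential expression over a gene panel.

    Per gene: two-sided Wilcoxon rank-sum across cells (exact-conditional
    for tiny groups, tie-corrected asymptotic otherwise), log2FC of
    pseudocount-stabilized group mean expression, percentage-point
    difference in expressing-cell fractions, and Bonferroni adjustment over
    the panel.  A gene absent from one group's matrix counts as all-zero.
    """
    a, b, panel = _align(expr_a, expr_b, genes, genes_b if genes_b is not None else genes)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both groups must contain cells")
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    pct_diff = 100.0 * ((a > 0).mean(axis=0) - (b > 0).mean(axis=0))
    n_genes = len(panel)
    if a.shape[0] + b.shape[0] <= exact_limit:
        p_raw = np.array([rank_sum_p(a[:, j], b[:, j]) for j in range(n_genes)])
    else:
        const = np.ptp(np.vstack([a, b]), axis=0) == 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p_raw = stats.mannwhitneyu(a, b, axis=0, method="asymptotic").pvalue
        p_raw = np.where(const | ~np.isfinite(p_raw), 1.0, p_raw)
    p_adj = np.minimum(1.0, p_raw * n_genes)
    return pd.DataFrame(
        {"gene": panel, "log2FC": log2fc, "pct_diff": pct_diff,
         "p_raw": p_raw, "p_adj": p_adj}
    )


def _group_split(cells, expr, group_col, positive, negative, cell_type, type_col):
    expr = _as_dense(expr)
    keep = np.ones(len(cells), dtype=bool)
    if cell_type is not None:
        keep = (cells[type_col] == cell_type).to_numpy()
    mask_a = keep & (cells[group_col] == positive).to_numpy()
    mask_b = keep & (cells[group_col] == negative).to_numpy()
    return expr, mask_a, mask_b


def loo_profiles(
    cells: pd.DataFrame,
    expr,
    genes: list[str],
    group_col: str = "group",
    sample_col: str = "sample",
    positive: str = RESPONDER,
    negative: str = NONRESPONDER,
    cell_type: str | None = "monocyte",
    type_col: str = "cell_type",
    deplete: str = "positive",
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Leave-one-out fold-change profiles over the gene panel.

    Returns a genes x profiles DataFrame whose first column, "Control", is
    the no-deletion log2FC vector, followed by one "<sample>_FC" column per
    single-sample deletion.  Deletions are taken in the responder group by
    default (``deplete`` in {"positive", "negative", "both"}); a deletion
    that would empty its group is skipped with a warning.
    """
    expr, mask_a, mask_b = _group_split(
        cells, expr, group_col, positive, negative, cell_type, type_col
    )
    samples = cells[sample_col].to_numpy()

    def fc(ma, mb):
        mean_a = expr[ma].mean(axis=0)
        mean_b = expr[mb].mean(axis=0)
        return np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("both groups must contain cells")
    groups_to_deplete = {
        "positive": [(positive, mask_a)],
        "negative": [(negative, mask_b)],
        "both": [(positive, mask_a), (negative, mask_b)],
    }[deplete]
    profiles = {"Control": fc(mask_a, mask_b)}
    for _, gmask in groups_to_deplete:
        deletable = sorted(set(samples[gmask]))
        if len(deletable) < 2:
            raise ValueError("need >= 2 samples in the depleted group")
        for s in deletable:
            ma = mask_a & (samples != s)
            mb = mask_b & (samples != s)
            if ma.sum() == 0 or mb.sum() == 0:
                warnings.warn(f"deleting sample {s!r} empties a group; skipped")
                continue
            profiles[f"{s}_FC"] = fc(ma, mb)
    return pd.DataFrame(profiles, index=pd.Index(genes, name="gene"))


def pca_outliers(
    profiles: pd.DataFrame,
    n_components: int = 2,
    z_cutoff: float = 3.0,
    control: str = "Control",
) -> dict:
    """Flag outlying deletion profiles in PCA space.

    Profiles (columns) are centered and projected onto the leading
    ``n_components`` principal components; each profile's Euclidean
    distance from the medoid is converted to a robust z-score (median/MAD)
    and profiles exceeding ``z_cutoff`` are flagged.  The control profile is
    never flagged.  Returns {"flagged": [profile names], "scores": Series}.
    """
    if profiles.shape[1] < 3:
        raise ValueError("need at least 3 profiles for outlier detection")
    X = profiles.to_numpy(dtype=float).T  # observations x genes
    Xc = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, s.size)
    scores = u[:, :k] * s[:k]
    d2 = ((scores[:, None, :] - scores[None, :, :]) ** 2).sum(axis=2)
    medoid = int(np.argmin(np.sqrt(d2).sum(axis=1)))
    d = np.sqrt(d2[:, medoid])
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    scale = 1.4826 * mad
    if scale <= 1e-12:
        span = np.abs(d - med).max()
        z = np.where(np.abs(d - med) > max(1e-9, 1e-6 * span), np.inf, 0.0)
    else:
        z = (d - med) / scale
    names = list(profiles.columns)
    flagged = [n for n, zi in zip(names, z) if zi > z_cutoff and n != control]
    return {"flagged": flagged, "scores": pd.Series(z, index=names, name="robust_z")}


@dataclass
class OverlapResult:
    similar: bool
    overlap_up: float
    overlap_down: float
    k_up: int
    k_down: int
    k_requested: int


def _top_genes(deg: pd.DataFrame, direction: int, k: int, sig_level: float):
    sig = deg[(deg["p_adj"] < sig_level) & (np.sign(deg["log2FC"]) == direction)]
    ordered = sig.sort_values(
        ["log2FC", "gene"], ascending=[direction < 0, True]
    )
    return list(ordered["gene"])


def overlap_check(
    control: pd.DataFrame,
    test: pd.DataFrame,
    k: int = 100,
    sig_level: float = 0.05,
    threshold: float = 0.8,
) -> OverlapResult:
    """Compare top-k up/down DEG lists of Control vs Test.

    Genes qualify when Bonferroni-adjusted p < ``sig_level``; ranking is by
    signed log2FC.  When fewer than ``k`` genes qualify, k is reduced to the
    available count (recorded in the result).  The verdict is "similar" when
    the overlap fraction reaches ``threshold`` in BOTH directions.
    """
    overlaps, ks = [], []
    for direction in (1, -1):
        gc = _top_genes(control, direction, k, sig_level)
        gt = _top_genes(test, direction, k, sig_level)
        k_eff = min(k, len(gc), len(gt))
        if k_eff == 0:
            overlaps.append(1.0 if not gc and not gt else 0.0)
        else:
            overlaps.append(len(set(gc[:k_eff]) & set(gt[:k_eff])) / k_eff)
        ks.append(k_eff)
    similar = overlaps[0] >= threshold and overlaps[1] >= threshold
    return OverlapResult(
        similar=similar, overlap_up=overlaps[0], overlap_down=overlaps[1],
        k_up=ks[0], k_down=ks[1], k_requested=k,
    )


@dataclass
class CDDResults:
    """Outcome of the case-deletion screen."""

    retained: list[str]
    removed: list[str]
    flagged: list[str]
    report: pd.DataFrame
    outlier_scores: pd.Series

    def summary(self) -> str:
        lines = [
            f"Case-deletion diagnostics: {len(self.retained)} retained, "
            f"{len(self.removed)} removed "
            f"({len(self.flagged)} flagged in PCA)",
        ]
        if len(self.report):
            lines.append(self.report.to_string(index=False))
        return "\n".join(lines)


class CaseDeletionDiagnostics:
    """Leave-one-out DEG-profile diagnostics over a per-cell dataset.

    fit() runs the full screen: LOO fold-change profiles, PCA outlier
    flagging, and the top-k overlap retention decision per flagged sample.
    """

    def __init__(
        self,
        cells: pd.DataFrame,
        expr,
        genes: list[str],
        group_col: str = "group",
        sample_col: str = "sample",
        positive: str = RESPONDER,
        negative: str = NONRESPONDER,
        cell_type: str | None = "monocyte",
        deplete: str = "positive",
        k: int = 100,
        sig_level: float = 0.05,
        overlap_threshold: float = 0.8,
        z_cutoff: float = 3.0,
        n_components: int = 2,
    ):
        self.cells = cells
        self.expr = _as_dense(expr)
        self.genes = list(genes)
        self.opts = dict(
            group_col=group_col, sample_col=sample_col, positive=positive,
            negative=negative, cell_type=cell_type, deplete=deplete,
        )
        self.k = k
        self.sig_level = sig_level
        self.overlap_threshold = overlap_threshold
        self.z_cutoff = z_cutoff
        self.n_components = n_components

    def _degs_without(self, drop_sample: str | None) -> pd.DataFrame:
        o = self.opts
        cells, expr = self.cells, self.expr
        keep = np.ones(len(cells), dtype=bool)
        if o["cell_type"] is not None:
            keep &= (cells["cell_type"] == o["cell_type"]).to_numpy()
        if drop_sample is not None:
            keep &= (cells[o["sample_col"]] != drop_sample).to_numpy()
        mask_a = keep & (cells[o["group_col"]] == o["positive"]).to_numpy()
        mask_b = keep & (cells[o["group_col"]] == o["negative"]).to_numpy()
        return compute_degs(expr[mask_a], expr[mask_b], self.genes)

    def fit(self) -> CDDResults:
        o = self.opts
        profiles = loo_profiles(
            self.cells, self.expr, self.genes, group_col=o["group_col"],
            sample_col=o["sample_col"], positive=o["positive"],
            negative=o["negative"], cell_type=o["cell_type"], deplete=o["deplete"],
        )
        out = pca_outliers(profiles, n_components=self.n_components,
                           z_cutoff=self.z_cutoff)
        flagged_samples = [n[: -len("_FC")] for n in out["flagged"]]
        control_deg = self._degs_without(None)
        rows, removed = [], []
        for s in flagged_samples:
            test_deg = self._degs_without(s)
            res = overlap_check(
                control_deg, test_deg, k=self.k, sig_level=self.sig_level,
                threshold=self.overlap_threshold,
            )
            decision = "retained" if res.similar else "removed"
            if not res.similar:
                removed.append(s)
            rows.append(
                {"sample": s, "flagged": True, "overlap_up": res.overlap_up,
                 "overlap_down": res.overlap_down, "k_up": res.k_up,
                 "k_down": res.k_down, "decision": decision}
            )
        in_scope = self.cells
        if o["cell_type"] is not None:
            in_scope = in_scope[in_scope["cell_type"] == o["cell_type"]]
        all_samples = sorted(in_scope[o["sample_col"]].unique())
        retained = [s for s in all_samples if s not in removed]
        return CDDResults(
            retained=retained, removed=removed, flagged=flagged_samples,
            report=pd.DataFrame(
                rows, columns=["sample", "flagged", "overlap_up", "overlap_down",
                               "k_up", "k_down", "decision"],
            ),
            outlier_scores=out["scores"],
        )


def run_cdd(cells: pd.DataFrame, expr, genes: list[str], **kwargs) -> CDDResults:
    """Run the full case-deletion screen; see CaseDeletionDiagnostics."""
    return CaseDeletionDiagnostics(cells, expr, genes, **kwargs).fit()
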