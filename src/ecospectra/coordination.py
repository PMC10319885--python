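"""Trait/property coordination analysis: standardized PCA with bootstrap errors.

Three pre-registered variable sets probe whether well-known leaf- and
plant-level coordination axes survive aggregation to the ecosystem scale:

* ``leaf_economics``  — wNmass, wLL, wLMA, GPPsat, RECOmax
* ``global_spectrum`` — wNmass, wLMA, GPPsat, wSSD, LAImax, Hc
* ``least_cost``      — PNUE, WUEt, Gsmax, EF, Ta, Hc, LAImax

Each analysis z-transforms the variables, decomposes the correlation matrix,
tests how many components are statistically meaningful with a sequential
permutation test, and attaches standard errors to the explained variances,
loadings (variable-component correlations) and contributions via a 499-
replicate row bootstrap.  The analysis can be rerun on all sites, forest
sites only, or evergreen needleleaf forest sites only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HYPOTHESES: dict[str, tuple[str, ...]] = {
    "leaf_economics": ("wNmass", "wLL", "wLMA", "GPPsat", "RECOmax"),
    "global_spectrum": ("wNmass", "wLMA", "GPPsat", "wSSD", "LAImax", "Hc"),
    "least_cost": ("PNUE", "WUEt", "Gsmax", "EF", "Ta", "Hc", "LAImax"),
}

SUBSETS: dict[str, frozenset | None] = {
    "all": None,
    "forests": frozenset({"DBF", "EBF", "ENF", "MF"}),
    "ENF": frozenset({"ENF"}),
}

DEFAULT_N_BOOT = 499


def assemble_matrix(efp_table: pd.DataFrame, hypothesis: str,
                    subset: str = "all") -> pd.DataFrame:
    """Complete-case site x variable matrix for one hypothesis and site subset."""
    if hypothesis not in HYPOTHESES:
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    if subset not in SUBSETS:
        raise ValueError(f"unknown subset {subset!r}")
    df = efp_table
    keep_igbp = SUBSETS[subset]
    if keep_igbp is not None:
        df = df[df["IGBP"].isin(keep_igbp)]
        if df.empty:
            raise ValueError(f"no sites in subset {subset!r}")
    variables = list(HYPOTHESES[hypothesis])
    mat = df.set_index("site_id")[variables].dropna() if "site_id" in df.columns \
        else df[variables].dropna()
    if len(mat) < 3:
        raise ValueError(f"only {len(mat)} complete sites for {hypothesis}/{subset}")
    return mat


def ztransform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-transformation (mean 0, sample SD 1, ddof=1)."""
    sd = matrix.std(ddof=1)
    constant = sd[~(sd > 0)].index.tolist()
    if constant:
        raise ValueError(f"constant column(s): {constant}")
    return (matrix - matrix.mean()) / sd


@dataclass
class PCAResult:
    """Eigendecomposition of the correlation matrix, FactoMineR-style outputs.

    loadings are variable-component correlations (eigenvector * sqrt(lambda)),
    contributions are 100 * loading^2 / lambda (summing to 100 per component),
    explained variance is lambda / p * 100.
    """

    eigenvalues: np.ndarray
    explained_variance: np.ndarray          # % per component
    loadings: pd.DataFrame                  # variables x components
    contributions: pd.DataFrame             # variables x components, %
    scores: pd.DataFrame                    # sites x components
    n_sites: int
    n_retained: int | None = None
    zero_components: list[int] = field(default_factory=list)


def pca(z: pd.DataFrame) -> PCAResult:
    """PCA of a z-transformed matrix via the correlation-matrix eigenproblem.

    Component signs are oriented so each component's largest-magnitude
    loading is positive.  Rank deficiency is tolerated: null components get
    zero eigenvalue/loadings and are flagged.
    """
    n, p = z.shape
    corr = z.to_numpy().T @ z.to_numpy() / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    zero = evals < 1e-10
    if zero.any():
        logger.warning("rank-deficient input: %d null component(s)", int(zero.sum()))
    evals = np.clip(evals, 0.0, None)
    load = evecs * np.sqrt(evals)
    # sign convention: largest |loading| per component positive
    for k in range(p):
        j = int(np.argmax(np.abs(load[:, k])))
        if load[j, k] < 0:
            load[:, k] *= -1.0
            evecs[:, k] *= -1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(evals > 0, 100.0 * load**2 / evals, 0.0)
    comp = [f"PC{k + 1}" for k in range(p)]
    return PCAResult(
        eigenvalues=evals,
        explained_variance=evals / p * 100.0,
        loadings=pd.DataFrame(load, index=z.columns, columns=comp),
        contributions=pd.DataFrame(contrib, index=z.columns, columns=comp),
        scores=pd.DataFrame(z.to_numpy() @ evecs, index=z.index, columns=comp),
        n_sites=n,
        zero_components=list(np.flatnonzero(zero)),
    )


def _rv_first_axis(e: np.ndarray) -> float:
    """Similarity between a matrix and its best rank-1 approximation.

    RV(E, E1) = s1^2 / sqrt(sum si^4) for singular values si; monotone in the
    share of variation the leading axis captures.
    """
    s = np.linalg.svd(e, compute_uv=False)
    s2 = s**2
    denom = np.sqrt(np.sum(s2**2))
    return float(s2[0] / denom) if denom > 0 else 0.0


def dray_dimension_test(z: pd.DataFrame, n_perm: int = 999, alpha: float = 0.05,
                        seed: int | None = None) -> int:
    """Number of statistically meaningful components (sequential permutation test).

    For k = 1, 2, ...: the k-th eigenvalue of the observed correlation matrix
    (equivalently, the gain in fit of the rank-k over the rank-(k-1)
    approximation) is compared against its null distribution from matrices
    whose columns are permuted independently of one another; testing stops at
    the first dimension whose permutation p-value exceeds ``alpha``, and the
    retained count is the number of dimensions before it.  Deterministic for
    a fixed seed.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    x = z.to_numpy()
    n, p = x.shape
    n_test = min(n - 1, p)
    obs = np.sort(np.linalg.svd(x, compute_uv=False))[::-1] ** 2
    null = np.empty((n_perm, n_test))
    for r in range(n_perm):
        perm = np.column_stack([x[rng.permutation(n), j] for j in range(p)])
        null[r] = np.sort(np.linalg.svd(perm, compute_uv=False))[::-1][:n_test] ** 2
    retained = 0
    for k in range(n_test):
        p_val = (np.sum(null[:, k] >= obs[k]) + 1) / (n_perm + 1)
        if p_val > alpha:
            break
        retained += 1
    return retained


@dataclass
class BootstrapResult:
    """Row-bootstrap spread of the PCA outputs (B replicates)."""

    n_boot: int
    seed: int | None
    se_explained_variance: np.ndarray
    se_loadings: pd.DataFrame
    se_contributions: pd.DataFrame
    median_explained_variance: np.ndarray
    median_loadings: pd.DataFrame
    median_contributions: pd.DataFrame
    replicate_explained_variance: np.ndarray      # B x p
    replicate_loadings: np.ndarray                # B x p x p
    replicate_contributions: np.ndarray           # B x p x p


def bootstrap_pca(matrix: pd.DataFrame, n_boot: int = DEFAULT_N_BOOT,
                  seed: int | None = None,
                  reference: PCAResult | None = None) -> BootstrapResult:
    """Substitution (row) bootstrap of the standardized PCA.

    Each replicate resamples sites with replacement at the original n,
    re-standardizes, and reruns the PCA; components are matched to the
    full-data solution by eigenvalue rank and their signs aligned by
    maximizing the dot product with the full-data loading vectors.  The
    standard error of every statistic is the SD over replicates.  Replicates
    that draw a constant column are redrawn (and logged).  Per-replicate
    substreams are spawned from the master seed, so increasing ``n_boot``
    never reshuffles earlier replicates.
    """
    if len(matrix) < 3:
        raise ValueError("bootstrap requires >= 3 rows")
    if reference is None:
        reference = pca(ztransform(matrix))
    n, p = matrix.shape
    ref_load = reference.loadings.to_numpy()
    streams = np.random.SeedSequence(seed).spawn(n_boot)
    ev = np.empty((n_boot, p))
    loads = np.empty((n_boot, p, p))
    contribs = np.empty((n_boot, p, p))
    for b, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        while True:
            idx = rng.integers(0, n, n)
            sample = matrix.iloc[idx]
            if (sample.std(ddof=1) > 0).all():
                break
            logger.info("bootstrap replicate %d drew a constant column; redrawn", b)
        res = pca(ztransform(sample))
        load = res.loadings.to_numpy().copy()
        for k in range(p):
            dot = float(load[:, k] @ ref_load[:, k])
            if dot < 0:
                load[:, k] *= -1.0
            if ref_load[:, k].any():
                denom = (np.linalg.norm(load[:, k]) * np.linalg.norm(ref_load[:, k]))
                if denom > 0 and abs(dot) / denom < 0.5:
                    logger.info("replicate %d PC%d weakly matches the full-data axis", b, k + 1)
        ev[b] = res.explained_variance
        loads[b] = load
        contribs[b] = res.contributions.to_numpy()
    comp = list(reference.loadings.columns)
    idxv = reference.loadings.index
    return BootstrapResult(
        n_boot=n_boot, seed=seed,
        se_explained_variance=ev.std(axis=0, ddof=1),
        se_loadings=pd.DataFrame(loads.std(axis=0, ddof=1), index=idxv, columns=comp),
        se_contributions=pd.DataFrame(contribs.std(axis=0, ddof=1), index=idxv, columns=comp),
        median_explained_variance=np.median(ev, axis=0),
        median_loadings=pd.DataFrame(np.median(loads, axis=0), index=idxv, columns=comp),
        median_contributions=pd.DataFrame(np.median(contribs, axis=0), index=idxv, columns=comp),
        replicate_explained_variance=ev,
        replicate_loadings=loads,
        replicate_contributions=contribs,
    )


class CoordinationPCA:
    """Model object for one hypothesis-specific ordination.

    Parameters
    ----------
    matrix : complete-case site x variable DataFrame (raw scale; the model
        z-transforms internally).  Use :meth:`from_efp_table` to build it
        from the site-level property table.
    """

    def __init__(self, matrix: pd.DataFrame, hypothesis: str | None = None,
                 subset: str = "all"):
        self.matrix = matrix
        self.hypothesis = hypothesis
        self.subset = subset
        self.exog_names = list(matrix.columns)

    @classmethod
    def from_efp_table(cls, efp_table: pd.DataFrame, hypothesis: str,
                       subset: str = "all") -> "CoordinationPCA":
        return cls(assemble_matrix(efp_table, hypothesis, subset), hypothesis, subset)

    def fit(self, n_boot: int = DEFAULT_N_BOOT, seed: int | None = None,
            n_perm: int = 999, alpha: float = 0.05,
            run_bootstrap: bool = True) -> "CoordinationPCAResults":
        z = ztransform(self.matrix)
        result = pca(z)
        result.n_retained = dray_dimension_test(z, n_perm=n_perm, alpha=alpha, seed=seed)
        boot = bootstrap_pca(self.matrix, n_boot=n_boot, seed=seed,
                             reference=result) if run_bootstrap else None
        return CoordinationPCAResults(self, result, boot)


class CoordinationPCAResults:
    """Fitted ordination: point estimates, bootstrap errors, dimensionality."""

    def __init__(self, model: CoordinationPCA, result: PCAResult,
                 bootstrap: BootstrapResult | None):
        self.model = model
        self.result = result
        self.bootstrap = bootstrap

    # convenience accessors -------------------------------------------------
    @property
    def eigenvalues(self) -> np.ndarray:
        return self.result.eigenvalues

    @property
    def explained_variance(self) -> np.ndarray:
        return self.result.explained_variance

    @property
    def loadings(self) -> pd.DataFrame:
        return self.result.loadings

    @property
    def contributions(self) -> pd.DataFrame:
        return self.result.contributions

    @property
    def scores(self) -> pd.DataFrame:
        return self.result.scores

    @property
    def n_retained(self) -> int | None:
        return self.result.n_retained

    def cumulative_explained(self, k: int) -> float:
        """Cumulative explained variance (%) of the first k components."""
        return float(self.explained_variance[:k].sum())

    def summary(self) -> str:
        r, b = self.result, self.bootstrap
        p = len(r.eigenvalues)
        name = self.model.hypothesis or "custom"
        lines = [
            "Coordination PCA Results",
            "=" * 64,
            f"Hypothesis: {name:<22s} Subset: {self.model.subset}",
            f"Sites:      {r.n_sites:<22d} Retained components: {r.n_retained}",
            "-" * 64,
            "Component   eigenvalue   explained %        SE",
        ]
        for k in range(p):
            se = f"{b.se_explained_variance[k]:10.2f}" if b else "         -"
            lines.append(f"PC{k + 1:<9d}{r.eigenvalues[k]:11.3f}{r.explained_variance[k]:13.1f}{se}")
        lines.append("-" * 64)
        lines.append("Loadings (variable-component correlation, +/- bootstrap SE)")
        header = "          " + "".join(f"{c:>16s}" for c in r.loadings.columns[:3])
        lines.append(header)
        for var in r.loadings.index:
            cells = []
            for c in r.loadings.columns[:3]:
                se = f"+/-{b.se_loadings.loc[var, c]:.2f}" if b else ""
                cells.append(f"{r.loadings.loc[var, c]:8.2f} {se:<7s}")
            lines.append(f"{var:<10s}" + "".join(cells))
        lines.append("=" * 64)
        return "\n".join(lines)

    def to_report(self) -> dict:
        """Machine-readable report of the fitted ordination."""
        r, b = self.result, self.bootstrap
        rep = {
            "schema_version": 1,
            "hypothesis": self.model.hypothesis,
            "subset": self.model.subset,
            "n_sites": r.n_sites,
            "sites": [str(s) for s in self.model.matrix.index],
            "variables": list(r.loadings.index),
            "n_retained": r.n_retained,
            "eigenvalues": r.eigenvalues.tolist(),
            "explained_variance": r.explained_variance.tolist(),
            "loadings": {v: r.loadings.loc[v].tolist() for v in r.loadings.index},
            "contributions": {v: r.contributions.loc[v].tolist() for v in r.contributions.index},
        }
        if b is not None:
            rep["bootstrap"] = {
                "n_boot": b.n_boot,
                "seed": b.seed,
                "se_explained_variance": b.se_explained_variance.tolist(),
                "median_explained_variance": b.median_explained_variance.tolist(),
                "se_loadings": {v: b.se_loadings.loc[v].tolist() for v in b.se_loadings.index},
                "se_contributions": {v: b.se_contributions.loc[v].tolist()
                                     for v in b.se_contributions.index},
            }
        return rep

    def save_report(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_report(), fh, indent=2)

    def plot_biplot(self, components=(0, 1), ax=None):
        """Scores + loading arrows for two components (requires matplotlib)."""
        import matplotlib.pyplot as plt

        r = self.result
        i, j = components
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        ax.scatter(r.scores.iloc[:, i], r.scores.iloc[:, j], s=12, alpha=0.6)
        scale = float(np.abs(r.scores.iloc[:, [i, j]].to_numpy()).max())
        for var in r.loadings.index:
            x, y = r.loadings.iloc[:, i][var] * scale, r.loadings.iloc[:, j][var] * scale
            ax.annotate("", xy=(x, y), xytext=(0, 0),
                        arrowprops=dict(arrowstyle="->", color="crimson"))
            ax.text(x * 1.06, y * 1.06, var, color="crimson", fontsize=9)
        ax.axhline(0, lw=0.5, color="gray")
        ax.axvline(0, lw=0.5, color="gray")
        ax.set_xlabel(f"PC{i + 1} ({r.explained_variance[i]:.1f}%)")
        ax.set_ylabel(f"PC{j + 1} ({r.explained_variance[j]:.1f}%)")
        return ax


def load_report(path) -> dict:
    """Read back a report written by :meth:`CoordinationPCAResults.save_report`."""
    with open(path) as fh:
        rep = json.load(fh)
    if rep.get("schema_version") != 1:
        raise ValueError("unknown report schema")
    return rep


def run_hypothesis(efp_table: pd.DataFrame, hypothesis: str, subset: str = "all",
                   n_boot: int = DEFAULT_N_BOOT, seed: int | None = None,
                   n_perm: int = 999, alpha: float = 0.05) -> CoordinationPCAResults:
    """Assemble, standardize, decompose, test dimensionality, bootstrap."""
    model = CoordinationPCA.from_efp_table(efp_table, hypothesis, subset)
    return model.fit(n_boot=n_boot, seed=seed, n_perm=n_perm, alpha=alpha)
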