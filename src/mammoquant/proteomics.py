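"""Label-free proteomic screen statistics.

Operates on a proteins x samples table of relative abundances (integrated
extracted-ion-chromatogram areas). Missing proteins appear as exact zeros;
the table carries an ``original_zero`` flag grid so that observation-based
filters keep working after imputation.

Preprocessing follows the standard label-free recipe:

1. ``impute_zeros`` — zeros become half the global minimum positive
   intensity;
2. ``filter_group_zeros`` — drop proteins with more than ``max_zeros``
   original zeros in any single sample group;
3. ``eic_normalize`` — divide each sample by its summed intensity so
   columns are relative abundances.

Downstream: Welch (heteroscedastic) t-tests with q-value FDR and a ±10
log2 sentinel for proteins observed in only one condition; correlation-
distance average-linkage clustering of sample profiles; a bootstrap
random-forest classifier that scores samples against two reference
developmental stages; and the group-comparison tests used for bar-graph
and imaging data (ANOVA + Tukey-Kramer, Wilcoxon rank-sum,
Kruskal-Wallis + Dunn).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list, to_tree
from scipy.spatial.distance import pdist
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError

LOG2_SENTINEL = 10.0


@dataclass
class AbundanceMatrix:
    """Proteins x samples intensity table with group labels."""

    values: np.ndarray
    protein_ids: list[str]
    sample_ids: list[str]
    group_labels: list[str]
    original_zero: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_prot, n_samp = self.values.shape
        if len(self.protein_ids) != n_prot or len(self.sample_ids) != n_samp \
                or len(self.group_labels) != n_samp:
            raise ParameterError("inconsistent matrix shapes/labels")
        if (self.values < 0).any():
            raise ParameterError("abundances must be non-negative")
        if self.original_zero is None:
            self.original_zero = self.values == 0
        self.original_zero = np.asarray(self.original_zero, dtype=bool)
        if self.original_zero.shape != self.values.shape:
            raise ParameterError("original_zero shape mismatch")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.group_labels:
            seen.setdefault(g, None)
        return list(seen)

    def group_columns(self, label: str) -> np.ndarray:
        cols = np.array([i for i, g in enumerate(self.group_labels)
                         if g == label])
        if cols.size == 0:
            raise ParameterError(f"no samples in group {label!r}")
        return cols

    def subset_group(self, label: str) -> "AbundanceMatrix":
        cols = self.group_columns(label)
        return AbundanceMatrix(
            values=self.values[:, cols],
            protein_ids=list(self.protein_ids),
            sample_ids=[self.sample_ids[i] for i in cols],
            group_labels=[self.group_labels[i] for i in cols],
            original_zero=self.original_zero[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids,
                            columns=self.sample_ids)

    def to_tsv(self, path, groups_path=None) -> None:
        self.to_frame().rename_axis("protein_id").to_csv(path, sep="\t")
        if groups_path is not None:
            import json
            with open(groups_path, "w") as fh:
                json.dump(dict(zip(self.sample_ids, self.group_labels)), fh,
                          indent=1)

    @classmethod
    def from_tsv(cls, path, groups_path) -> "AbundanceMatrix":
        import json
        df = pd.read_csv(path, sep="\t", index_col=0)
        with open(groups_path) as fh:
            groups = json.load(fh)
        return cls(values=df.to_numpy(float),
                   protein_ids=[str(i) for i in df.index],
                   sample_ids=[str(c) for c in df.columns],
                   group_labels=[groups[str(c)] for c in df.columns])


def impute_zeros(m: AbundanceMatrix) -> AbundanceMatrix:
    """Replace zeros by half the global minimum positive intensity."""
    pos = m.values[m.values > 0]
    if pos.size == 0:
        raise ParameterError("matrix has no positive values")
    fill = pos.min() / 2.0
    values = np.where(m.values == 0, fill, m.values)
    return replace(m, values=values, original_zero=m.original_zero.copy(),
                   protein_ids=list(m.protein_ids),
                   sample_ids=list(m.sample_ids),
                   group_labels=list(m.group_labels))


def filter_group_zeros(m: AbundanceMatrix,
                       max_zeros_per_group: int = 2) -> AbundanceMatrix:
    """Drop proteins whose original zeros exceed the cap in any one group.

    The rule inspects pre-imputation zeros (``original_zero``), never the
    current values.
    """
    keep = np.ones(len(m.protein_ids), dtype=bool)
    for g in m.groups:
        cols = m.group_columns(g)
        keep &= m.original_zero[:, cols].sum(axis=1) <= max_zeros_per_group
    return AbundanceMatrix(
        values=m.values[keep],
        protein_ids=[p for p, k in zip(m.protein_ids, keep) if k],
        sample_ids=list(m.sample_ids),
        group_labels=list(m.group_labels),
        original_zero=m.original_zero[keep])


def eic_normalize(m: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each sample by its summed intensity (columns sum to 1)."""
    colsum = m.values.sum(axis=0)
    if (colsum <= 0).any():
        raise ParameterError("every sample must have positive total intensity")
    return replace(m, values=m.values / colsum,
                   original_zero=m.original_zero.copy(),
                   protein_ids=list(m.protein_ids),
                   sample_ids=list(m.sample_ids),
                   group_labels=list(m.group_labels))


def qvalues(p_list, method: str = "bh") -> np.ndarray:
    """False-discovery-rate q-values for a list of p-values.

    ``bh`` is Benjamini-Hochberg step-up; ``storey`` additionally estimates
    the null proportion pi0 with the cubic-smoother recipe and scales the
    BH values by it.
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ParameterError("p-values must lie in [0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return q
    if method != "storey":
        raise ParameterError(f"unknown q-value method {method!r}")
    lam = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(p > l).mean() / (1 - l) for l in lam])
    coef = np.polyfit(lam, pi0_lam, deg=3)
    pi0 = float(np.clip(np.polyval(coef, lam[-1]), 1e-8, 1.0))
    return np.minimum(q * pi0, 1.0)


@dataclass
class DifferentialResult:
    """Per-protein Welch-test table for one pairwise comparison."""

    table: pd.DataFrame  # protein_id, mean_a, mean_b, t, p, q, log2_ratio,
                         # significant
    group_a: str
    group_b: str
    min_obs: int

    def __len__(self) -> int:
        return len(self.table)


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate: no variance anywhere; equal means are "no evidence"
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def differential(
    ma: AbundanceMatrix,
    mb: AbundanceMatrix,
    min_obs: int = 3,
    alpha: float = 0.05,
    log2_cut: float = 2.0,
    q_method: str = "bh",
) -> DifferentialResult:
    """Pairwise differential abundance between two sample groups.

    Proteins observed (nonzero before imputation) in fewer than ``min_obs``
    of the pooled samples are excluded. Per protein: Welch two-tailed
    t-test, q-value FDR over the tested set, and the log2 ratio of group
    means (A over B). A protein whose original values are all zero in
    exactly one group gets the ±10 sentinel instead (uniquely observed).
    A protein is called significant when p < ``alpha`` or
    \\|log2 ratio\\| >= ``log2_cut`` (4-fold by default).
    """
    if ma.values.shape[1] < 2 or mb.values.shape[1] < 2:
        raise ParameterError("each group needs at least 2 samples")
    if list(ma.protein_ids) != list(mb.protein_ids):
        raise ParameterError("protein rows must match between groups")

    obs_a = (~ma.original_zero).sum(axis=1)
    obs_b = (~mb.original_zero).sum(axis=1)
    tested = np.nonzero(obs_a + obs_b >= min_obs)[0]

    rows = []
    for i in tested:
        a, b = ma.values[i], mb.values[i]
        t, p = _welch(a, b)
        mean_a, mean_b = float(a.mean()), float(b.mean())
        zero_a = ma.original_zero[i].all()
        zero_b = mb.original_zero[i].all()
        if zero_a and not zero_b:
            l2 = -LOG2_SENTINEL
        elif zero_b and not zero_a:
            l2 = LOG2_SENTINEL
        else:
            l2 = float(np.clip(np.log2(mean_a / mean_b),
                               -LOG2_SENTINEL, LOG2_SENTINEL))
        rows.append((ma.protein_ids[i], mean_a, mean_b, t, p, l2))
    table = pd.DataFrame(rows, columns=[
        "protein_id", "mean_a", "mean_b", "t", "p", "log2_ratio"])
    table["q"] = qvalues(table["p"].to_numpy(), method=q_method) \
        if len(table) else []
    table["significant"] = (table["p"] < alpha) | \
        (table["log2_ratio"].abs() >= log2_cut)
    table = table[["protein_id", "mean_a", "mean_b", "t", "p", "q",
                   "log2_ratio", "significant"]]
    def _label(m: AbundanceMatrix, fallback: str) -> str:
        return m.group_labels[0] if len(set(m.group_labels)) == 1 else fallback

    return DifferentialResult(table=table, group_a=_label(ma, "A"),
                              group_b=_label(mb, "B"), min_obs=min_obs)


@dataclass
class SampleDendrogram:
    linkage: np.ndarray
    sample_ids: list[str]

    @property
    def leaf_order(self) -> list[str]:
        return [self.sample_ids[i] for i in leaves_list(self.linkage)]

    def to_newick(self) -> str:
        tree = to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.6g}"
            kids = ",".join(rec(c, node.dist)
                            for c in (node.left, node.right))
            return f"({kids}):{length:.6g}"

        root = tree
        kids = ",".join(rec(c, root.dist) for c in (root.left, root.right))
        return f"({kids});"


def correlation_cluster(m: AbundanceMatrix) -> SampleDendrogram:
    """Average-linkage clustering of samples, distance = 1 - Pearson r."""
    if m.values.shape[1] < 2:
        raise ParameterError("need at least two samples")
    profiles = m.values.T
    if (profiles.std(axis=1) == 0).any():
        raise ParameterError("constant sample profile: correlation undefined")
    d = pdist(profiles, metric="correlation")
    return SampleDendrogram(linkage=average(d), sample_ids=list(m.sample_ids))


@dataclass
class StageClassifierReport:
    """Random-forest stage scores for every sample."""

    classes: list[str]
    probabilities: pd.DataFrame  # samples x classes
    oob_accuracy: float
    n_trees: int
    seed: int


def rf_stage_classify(
    train: AbundanceMatrix,
    score: AbundanceMatrix,
    n_trees: int = 5000,
    seed: int = 0,
) -> StageClassifierReport:
    """Score samples against two reference stages with a bagged forest.

    The forest (bootstrap resampling, random sqrt-feature subsets) is
    trained on the two labelled groups of ``train``; every sample of
    ``score`` receives the fraction of trees voting for each class, plus
    the out-of-bag accuracy of the trained model.
    """
    labels = np.asarray(train.group_labels)
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ParameterError("training data must contain exactly 2 classes")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ParameterError(f"class {c!r} needs at least 2 samples")
    if list(train.protein_ids) != list(score.protein_ids):
        raise ParameterError("train/score protein rows must match")
    clf = RandomForestClassifier(
        n_estimators=n_trees, bootstrap=True, oob_score=True,
        max_features="sqrt", random_state=seed)
    clf.fit(train.values.T, labels)
    probs = clf.predict_proba(score.values.T)
    cols = list(clf.classes_)
    return StageClassifierReport(
        classes=cols,
        probabilities=pd.DataFrame(probs, index=score.sample_ids,
                                   columns=cols),
        oob_accuracy=float(clf.oob_score_),
        n_trees=n_trees, seed=seed)


# --- group-comparison tests used for bar-graph / imaging data ------------

def _dunn(groups: list[np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based post-hoc z-tests with tie correction."""
    all_vals = np.concatenate(groups)
    n = all_vals.size
    ranks = stats.rankdata(all_vals)
    split = np.cumsum([g.size for g in groups])[:-1]
    group_ranks = np.split(ranks, split)
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    k = len(groups)
    m_comp = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            ni, nj = groups[i].size, groups[j].size
            z = (group_ranks[i].mean() - group_ranks[j].mean()) / \
                np.sqrt(var_base * (1 / ni + 1 / nj))
            p = 2 * stats.norm.sf(abs(z))
            rows.append((i, j, float(z), float(p),
                         float(min(1.0, p * m_comp))))
    return pd.DataFrame(rows, columns=["group_i", "group_j", "z", "p",
                                       "p_bonferroni"])


def group_compare(groups: list, design: str) -> dict:
    """Dispatch the study's group-comparison tests.

    designs: ``anova_tukey`` (one-way ANOVA + Tukey-Kramer pairwise,
    unequal n supported), ``wilcoxon`` (two-sided rank-sum, exact for small
    untied samples), ``kruskal_dunn`` (tie-corrected Kruskal-Wallis +
    Dunn's z-tests).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if design == "wilcoxon":
        if len(gs) != 2:
            raise ParameterError("wilcoxon compares exactly 2 groups")
        res = stats.mannwhitneyu(gs[0], gs[1], alternative="two-sided",
                                 method="auto")
        return {"design": design, "statistic": float(res.statistic),
                "p": float(res.pvalue)}
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ParameterError("need >= 2 groups with >= 2 observations")
    if design == "anova_tukey":
        if np.ptp(np.concatenate(gs)) == 0:
            pairwise = pd.DataFrame(
                [(i, j, 1.0) for i in range(len(gs))
                 for j in range(i + 1, len(gs))],
                columns=["group_i", "group_j", "p_adj"])
            return {"design": design, "F": 0.0, "p": 1.0,
                    "pairwise": pairwise}
        F, p = stats.f_oneway(*gs)
        hsd = stats.tukey_hsd(*gs)
        rows = [(i, j, float(hsd.pvalue[i, j]))
                for i in range(len(gs)) for j in range(i + 1, len(gs))]
        return {"design": design, "F": float(F), "p": float(p),
                "pairwise": pd.DataFrame(rows, columns=["group_i", "group_j",
                                                        "p_adj"])}
    if design == "kruskal_dunn":
        H, p = stats.kruskal(*gs)
        return {"design": design, "H": float(H), "p": float(p),
                "pairwise": _dunn(gs)}
    raise ParameterError(f"unknown design {design!r}")
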