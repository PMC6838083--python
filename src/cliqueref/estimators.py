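"""scikit-learn-compatible estimators over the functional core.

These wrap the pipeline pieces in fit/transform objects so they compose
with sklearn ``Pipeline`` and model selection:

* :class:`EquivalenceCliqueSelector` — a feature selector: ``fit(X, y)`` on
  a samples x genes Cq frame with group labels ``y`` runs all pairwise
  equivalence tests, builds the graph and selects the reference genes;
  ``transform(X)`` keeps only the selected gene columns.
* :class:`GeNormRanker` / :class:`NormFinderRanker` — fit-only estimators
  exposing the stability values and ranking as fitted attributes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .calibrate import CalibrationSpec, calibrate_cutoff, estimate_residual_sd
from .cq_data import CqMatrix
from .equivalence import all_pairs
from .graph_select import build_graph, select_reference_genes
from .rankers import genorm_rank, normfinder_rank

__all__ = ["EquivalenceCliqueSelector", "GeNormRanker", "NormFinderRanker"]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional (samples x genes)")
    return pd.DataFrame(X, columns=[f"G{j + 1:02d}" for j in range(X.shape[1])])


def _as_matrix(X, y) -> CqMatrix:
    values = _as_frame(X)
    if y is None:
        raise ValueError("group labels y are required")
    groups = pd.Series(np.asarray(y, dtype=object), index=values.index,
                       name="group")
    return CqMatrix(values=values, groups=groups)


class EquivalenceCliqueSelector(TransformerMixin, BaseEstimator):
    """Select reference genes by pairwise equivalence tests + maximum cliques.

    Parameters
    ----------
    delta : float, default 0.5
        Half-width of the equivalence region on the Cq scale (0.5 cycles
        corresponds to a 2**0.5 ~ 1.414 fold change at 100 % efficiency).
    cutoff : float or "calibrate", default "calibrate"
        Per-pair p-value threshold for adding an edge.  ``"calibrate"`` runs
        the Monte-Carlo fence-null calibration with a residual SD estimated
        from the data, targeting ``fwer``.
    fwer : float, default 0.05
        Target probability of any spurious >= 3-gene clique under the
        no-equivalence null (used only when calibrating).
    n_sim : int, default 10_000
        Number of null simulations for calibration.
    min_reliable_clique : int, default 4
        Smallest maximum-clique size considered a reliable selection.
    alpha : float, default 0.05
        Level used for the reported confidence intervals (1 - 2*alpha).
    random_state : int, default 0
        Seed for the calibration simulations.

    Attributes
    ----------
    cutoff_ : float
        The threshold actually used (calibrated or explicit).
    pairs_ : DataFrame
        The pairwise TOST table.
    graph_ : networkx.Graph
        The equivalence graph.
    selection_ : ReferenceSelection
    selected_genes_ : tuple of str
    support_ : boolean ndarray over input gene order
    """

    def __init__(self, delta: float = 0.5, cutoff="calibrate",
                 fwer: float = 0.05, n_sim: int = 10_000,
                 min_reliable_clique: int = 4, alpha: float = 0.05,
                 random_state: int = 0):
        self.delta = delta
        self.cutoff = cutoff
        self.fwer = fwer
        self.n_sim = n_sim
        self.min_reliable_clique = min_reliable_clique
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y=None):
        matrix = _as_matrix(X, y)
        self.feature_names_in_ = np.asarray(matrix.genes, dtype=object)
        self.n_features_in_ = len(self.feature_names_in_)
        if self.cutoff == "calibrate":
            n1 = int(np.sum(matrix.groups == matrix.group_levels()[0]))
            n2 = len(matrix.samples) - n1
            spec = CalibrationSpec(
                n_genes=self.n_features_in_, group_sizes=(n1, n2),
                delta=self.delta,
                residual_sd=estimate_residual_sd(matrix),
                n_sim=self.n_sim, target_fwer=self.fwer,
                seed=self.random_state)
            self.calibration_ = calibrate_cutoff(spec)
            self.cutoff_ = self.calibration_.cutoff
        else:
            self.calibration_ = None
            self.cutoff_ = float(self.cutoff)
        self.pairs_ = all_pairs(matrix, self.delta, alpha=self.alpha)
        self.graph_ = build_graph(self.pairs_, self.cutoff_, delta=self.delta)
        self.selection_ = select_reference_genes(
            self.graph_, self.min_reliable_clique)
        self.selected_genes_ = self.selection_.selected
        sel = set(self.selected_genes_)
        self.support_ = np.array([g in sel for g in self.feature_names_in_])
        return self

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "support_")
        return np.flatnonzero(self.support_) if indices else self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        values = _as_frame(X)
        if list(values.columns) != list(self.feature_names_in_):
            values = values[list(self.feature_names_in_)]
        return values.loc[:, self.support_]


class GeNormRanker(BaseEstimator):
    """geNorm stepwise stability ranking as a fit-only estimator.

    Fitted attributes: ``m_values_`` (Series, gene -> M at removal),
    ``ranking_`` (most stable first; first two are an unordered pair),
    ``exclusion_trace_`` (removal order, worst first), ``table_``.
    """

    def __init__(self, strict: bool = False):
        self.strict = strict

    def fit(self, X, y=None):
        values = _as_frame(X)
        result = genorm_rank(values, strict=self.strict)
        self.table_ = result.table
        self.ranking_ = result.ranking
        self.exclusion_trace_ = result.exclusion_trace
        self.m_values_ = result.table.set_index("gene")["stability"]
        self.feature_names_in_ = np.asarray(list(values.columns), dtype=object)
        self.n_features_in_ = len(self.feature_names_in_)
        return self


class NormFinderRanker(BaseEstimator):
    """NormFinder model-based stability ranking as a fit-only estimator.

    Requires group labels ``y`` (exactly two groups).  Fitted attributes:
    ``stability_`` (Series, gene -> rho), ``ranking_``, ``table_``.
    """

    def __init__(self, strict: bool = False):
        self.strict = strict

    def fit(self, X, y=None):
        values = _as_frame(X)
        result = normfinder_rank(values, groups=y, strict=self.strict)
        self.table_ = result.table
        self.ranking_ = result.ranking
        self.stability_ = result.table.set_index("gene")["stability"]
        self.feature_names_in_ = np.asarray(list(values.columns), dtype=object)
        self.n_features_in_ = len(self.feature_names_in_)
        return self
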