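"""subs2coal: convert a substitutions/site tree with concordance factors
into an ultrametric tree in coalescent units.

Internal branches: a quartet concordance factor estimates
CF(T) = 1 - (2/3) exp(-T) with T the branch length in coalescent units, so
T = -ln((3/2)(1 - CF)) recovers each internal branch length directly.
Tip branches carry no concordance factor, so the conversion is learned by
ordinary least squares of T on the substitutions/site length over the
usable internal branches, and tips are predicted from the fitted line
(optionally from the bounds of the t-based 95% prediction interval).
Finally the tree is smoothed to ultrametricity, either by redistributing
branch lengths evenly along each root-to-tip path or by extending tip
branches while preserving internal ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Tuple

import dendropy
import numpy as np
import statsmodels.api as sm

__all__ = [
    "CFTree",
    "ConversionFit",
    "cf_to_coalescent_length",
    "coalescent_length_to_cf",
    "fit_conversion",
    "predict_tips",
    "smooth",
    "subs2coal",
]


class ConversionError(ValueError):
    pass


def _parse_cf(label: str | None) -> float | None:
    """Concordance factor from an internal-node label.

    Accepts plain numbers and slash-separated label stacks (first numeric
    field wins).  Values above 1 are treated as percentages.
    """
    if label is None or label == "":
        return None
    for part in str(label).split("/"):
        try:
            val = float(part)
        except ValueError:
            continue
        if val > 1.0:
            warnings.warn(
                f"concordance factor {val} > 1 interpreted as a percentage")
            val /= 100.0
        return val
    return None


class CFTree:
    """A rooted tree in substitutions/site with CF-labelled internal nodes."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree

    @classmethod
    def from_newick(cls, newick: str) -> "CFTree":
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True,
                                 suppress_internal_node_taxa=True)
        return cls(tree)

    def internal_points(self) -> Tuple[np.ndarray, np.ndarray]:
        """(subs/site lengths, coalescent lengths) of usable internal branches."""
        xs, ys = [], []
        for nd in self.tree.preorder_internal_node_iter():
            if nd.parent_node is None:
                continue
            cf = _parse_cf(nd.label)
            if cf is None or nd.edge.length in (None, 0):
                continue
            if cf <= 1.0 / 3.0:
                warnings.warn(
                    f"concordance factor {cf:.3g} <= 1/3 (star tree or worse): "
                    "branch excluded from the regression")
                continue
            xs.append(float(nd.edge.length))
            ys.append(cf_to_coalescent_length(cf))
        return np.asarray(xs), np.asarray(ys)


def cf_to_coalescent_length(cf: float | None = None, *,
                            complement: float | None = None) -> float:
    """Invert CF(T) = 1 - (2/3) e^{-T}: T = -ln((3/2)(1 - cf)).

    CFs at or above 1 are clamped just below 1 with a warning; values are
    normalized from percentages upstream.  For concordance factors very
    close to 1 the subtraction 1 - cf loses precision; passing the
    discordance ``complement`` (1 - cf) directly avoids that.
    """
    if complement is None:
        if cf >= 1.0:
            warnings.warn("concordance factor >= 1 clamped to 1 - 1e-9")
            cf = 1.0 - 1e-9
        complement = 1.0 - cf
    return float(-np.log(1.5 * complement))


def coalescent_length_to_cf(T: float, *, as_complement: bool = False) -> float:
    """CF(T) = 1 - (2/3) e^{-T}; with ``as_complement`` returns 1 - CF(T),
    which stays fully precise for long branches."""
    comp = (2.0 / 3.0) * float(np.exp(-T))
    return comp if as_complement else 1.0 - comp


@dataclass
class ConversionFit:
    """OLS fit of coalescent-unit length on substitutions/site length."""

    slope: float
    intercept: float
    r_squared: float  # adjusted
    n_points: int
    x_range: Tuple[float, float]
    _results: object = None

    def predict(self, x: np.ndarray, bound: str = "point") -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        pred = self._results.get_prediction(sm.add_constant(x, has_constant="add"))
        frame = pred.summary_frame(alpha=0.05)
        if bound == "point":
            out = frame["mean"].to_numpy()
        elif bound == "lower95":
            out = frame["obs_ci_lower"].to_numpy()
        elif bound == "upper95":
            out = frame["obs_ci_upper"].to_numpy()
        else:
            raise ConversionError(f"unknown bound {bound!r}")
        return out


def fit_conversion(tree: CFTree) -> ConversionFit:
    """Least-squares line T = intercept + slope * (subs/site length)."""
    x, y = tree.internal_points()
    if x.size < 3:
        raise ConversionError(
            f"need >= 3 usable internal branches for the regression, got {x.size}")
    if np.ptp(x) == 0:
        raise ConversionError("zero-variance predictor: all internal branches equal")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return ConversionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared_adj),
        n_points=int(x.size),
        x_range=(float(x.min()), float(x.max())),
        _results=res,
    )


def predict_tips(tree: CFTree, fit: ConversionFit, bound: str = "point",
                 floor: float = 1e-6) -> Dict[str, float]:
    """Tip branch lengths in coalescent units from the fitted line.

    Tips whose substitutions/site length falls outside the range of the
    regression's datapoints are flagged as extrapolations; negative
    predictions are floored at a small positive value.
    """
    labels, xs = [], []
    for lf in tree.tree.leaf_node_iter():
        labels.append(lf.taxon.label)
        xs.append(float(lf.edge.length or 0.0))
    xs = np.asarray(xs)
    lo, hi = fit.x_range
    for lab, x in zip(labels, xs):
        if x < lo or x > hi:
            warnings.warn(
                f"tip {lab!r} length {x:.4g} outside the fitted range "
                f"[{lo:.4g}, {hi:.4g}]: prediction requires extrapolation")
    pred = fit.predict(xs, bound=bound)
    out = {}
    for lab, val in zip(labels, pred):
        if val <= 0:
            warnings.warn(
                f"non-positive predicted length for tip {lab!r}; floored at {floor}")
            val = floor
        out[lab] = float(val)
    return out


# ---------------------------------------------------------------------------
# smoothing

def _depths(tree: dendropy.Tree) -> Dict[dendropy.Node, float]:
    depth = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            depth[nd] = 0.0
        else:
            depth[nd] = depth[nd.parent_node] + (nd.edge.length or 0.0)
    return depth


def smooth(tree: dendropy.Tree, method: str = "extend") -> dendropy.Tree:
    """Make a rooted tree ultrametric.

    ``redistribute`` reallocates each root-to-tip span evenly over the
    edges on the path (each edge below a node receives the node's
    remaining depth divided by one plus the maximum number of edges left
    to a leaf), so every tip ends at the same depth.  ``extend`` lengthens
    each tip branch by the difference between the maximum root-to-tip
    depth and its own, leaving internal branches untouched.
    """
    tree = tree.clone(depth=1)
    depth = _depths(tree)
    height = max(depth[lf] for lf in tree.leaf_node_iter())
    if method == "extend":
        for lf in tree.leaf_node_iter():
            lf.edge.length = (lf.edge.length or 0.0) + (height - depth[lf])
    elif method == "redistribute":
        levels: Dict[dendropy.Node, int] = {}
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                levels[nd] = 0
            else:
                levels[nd] = 1 + max(levels[c] for c in nd.child_nodes())
        remaining = {tree.seed_node: height}
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            span = remaining[nd.parent_node]
            nd.edge.length = span / (1 + levels[nd])
            remaining[nd] = span - nd.edge.length
    else:
        raise ConversionError(f"unknown smoothing method {method!r}")
    return tree


def subs2coal(cftree: CFTree, smoothing: str = "extend", tip_bound: str = "point",
              exclude_outgroup: str | None = None
              ) -> Tuple[dendropy.Tree, ConversionFit]:
    """Full conversion: CF internal branches, regression-predicted tips,
    then smoothing.  Returns the coalescent-unit tree and the fit report.

    With ``exclude_outgroup`` the named tip is removed before smoothing
    and re-grafted afterwards at a depth proportional to its original
    substitutions/site branch length (times the fitted slope).
    """
    fit = fit_conversion(cftree)
    tips = predict_tips(cftree, fit, bound=tip_bound)
    conv = cftree.tree.clone(depth=1)
    for nd in conv.preorder_node_iter():
        if nd.parent_node is None:
            continue
        if nd.is_leaf():
            nd.edge.length = tips[nd.taxon.label]
        else:
            cf = _parse_cf(nd.label)
            if cf is None or cf <= 1.0 / 3.0:
                # unusable CF: fall back to the regression line
                nd.edge.length = max(
                    float(fit.predict(np.array([nd.edge.length or 0.0]))[0]), 1e-6)
            else:
                nd.edge.length = cf_to_coalescent_length(cf)

    out_len = None
    if exclude_outgroup is not None:
        for lf in cftree.tree.leaf_node_iter():
            if lf.taxon.label == exclude_outgroup:
                out_len = float(lf.edge.length or 0.0)
        if out_len is None:
            raise ConversionError(f"outgroup {exclude_outgroup!r} not in tree")
        keep = [t for t in conv.taxon_namespace if t.label != exclude_outgroup]
        conv = conv.extract_tree_with_taxa(taxa=keep)
        conv.purge_taxon_namespace()

    sm_tree = smooth(conv, method=smoothing)

    if exclude_outgroup is not None:
        depth = _depths(sm_tree)
        in_height = max(depth[lf] for lf in sm_tree.leaf_node_iter())
        out_depth = out_len * fit.slope
        if out_depth <= in_height:
            warnings.warn(
                "outgroup re-graft depth does not exceed the ingroup height; "
                "placing it just above the ingroup root")
            out_depth = in_height * 1.05
        newick = sm_tree.as_string(
            schema="newick", suppress_rooting=True).strip().rstrip(";")
        grafted = (f"({newick}:{out_depth - in_height:.10g},"
                   f"{exclude_outgroup}:{out_depth:.10g});")
        sm_tree = dendropy.Tree.get(data=grafted, schema="newick",
                                  preserve_underscores=True)
    return sm_tree, fit
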