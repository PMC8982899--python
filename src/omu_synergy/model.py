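"""Model/Results interface for the whole prioritization pipeline.

:class:`SynergyModel` is constructed from the four data inputs (expression,
regulatory prior, TF-TF interactions, per-drug GRmax) plus tuning options;
``fit()`` executes the pipeline -- per-condition network inference,
differential modules against the control, OMU system construction, balance
point selection, the ILR -> GRmax ordinary least squares fit, and DGIS
scoring of all pairs -- and returns a :class:`SynergyResults` carrying every
intermediate artifact, the fitted coefficients and the candidate ranking,
with ``summary()`` and plotting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import balance as _balance
from . import diffmod as _diffmod
from . import grn as _grn
from . import omu as _omu
from . import scoring as _scoring
from .io_formats import EdgeList, ExpressionMatrix, GRTable


@dataclass
class PipelineOptions:
    """Tunables of the pipeline with their defaults.

    min_similarity: Jaccard threshold for merging differential modules into
        OMUs.  seed: drives every stochastic step (community detection visit
        order).  coexpr_blend: weight of the condition-specific rank-one term
        in the co-expression (0 = fully pooled).  centroid_bounds: mean-GRmax
        window for candidate balance points.  combine_rule: 'max' (operative
        definition) or 'sum'.  top_k: length of the reported candidate list.
    """

    seed: int = 1
    min_similarity: float = 0.25
    min_edges: int = 2
    denoise_quantile: float = 0.8
    coexpr_blend: float = 0.8
    gate_power: float = 2.0
    centroid_bounds: tuple[float, float] = (-0.5, 0.5)
    min_fraction: float = 0.9
    use_root: bool = False
    pseudocount: float = 0.05
    combine_rule: str = "max"
    top_k: int = 30
    grn_step: float = 0.1
    grn_tol: float = 1e-3
    grn_max_iter: int = 200


class SynergyModel:
    """Two-drug synergy prioritization from single-drug data."""

    def __init__(
        self,
        expression: ExpressionMatrix,
        prior: EdgeList,
        ppi: EdgeList,
        gr_table: GRTable,
        control_id: str = "control",
        options: PipelineOptions | None = None,
    ) -> None:
        if control_id not in expression.sample_ids:
            raise ValueError(f"control column {control_id!r} not in expression")
        missing = [s for s in expression.sample_ids
                   if s != control_id and s not in gr_table]
        if missing:
            raise ValueError(f"drugs without a GRmax entry: {missing}")
        self.expression = expression
        self.prior = prior
        self.ppi = ppi
        self.gr_table = gr_table
        self.control_id = control_id
        self.options = options or PipelineOptions()

    @classmethod
    def from_files(cls, expr_path, prior_path, ppi_path, gr_path,
                   control_id: str = "control",
                   options: PipelineOptions | None = None) -> "SynergyModel":
        from . import io_formats as io

        return cls(
            expression=io.read_expression(expr_path),
            prior=io.read_edge_list(prior_path),
            ppi=io.read_edge_list(ppi_path, symmetric=True),
            gr_table=io.read_gr_table(gr_path),
            control_id=control_id,
            options=options,
        )

    @classmethod
    def from_study(cls, study, options: PipelineOptions | None = None) -> "SynergyModel":
        """Build from a :class:`~omu_synergy.simulate.SyntheticStudy`."""
        return cls(
            expression=study.expression,
            prior=study.prior,
            ppi=study.ppi,
            gr_table=study.gr_table,
            control_id=study.config.control_id,
            options=options,
        )

    def fit(self) -> "SynergyResults":
        opt = self.options
        grns = _grn.infer_condition_grns(
            self.expression, self.prior, self.ppi, self.control_id,
            blend=opt.coexpr_blend, gate_power=opt.gate_power,
            step=opt.grn_step, tol=opt.grn_tol, max_iter=opt.grn_max_iter,
        )
        control_grn = grns[self.control_id]
        base = _diffmod.baseline_partition(control_grn, seed=opt.seed)

        modules: list[_diffmod.DifferentialModule] = []
        per_sample: dict[str, list[_diffmod.DifferentialModule]] = {}
        for sample, grn in grns.items():
            if sample == self.control_id:
                continue
            mods = _diffmod.differential_modules_for_sample(
                grn, control_grn, base, seed=opt.seed, min_edges=opt.min_edges,
                denoise_quantile=opt.denoise_quantile,
            )
            per_sample[sample] = mods
            modules.extend(mods)

        system = _omu.build_omu_system(modules, min_similarity=opt.min_similarity)
        _omu.assign_mean_grmax(system, self.gr_table, modules)
        vectors = {
            s: _omu.omu_vector(mods, system)
            for s, mods in per_sample.items() if mods
        }

        tree = _balance.cluster_omus(system)
        node, ilrs, r = _balance.select_balance_point(
            tree, vectors, self.gr_table,
            centroid_bounds=opt.centroid_bounds, min_fraction=opt.min_fraction,
            pseudocount=opt.pseudocount, use_root=opt.use_root,
        )
        linmod = _balance.fit_linear_model(ilrs, self.gr_table, node_id=node.node_id)

        scores = _scoring.score_all_pairs(
            vectors, linmod, node, rule=opt.combine_rule,
            pseudocount=opt.pseudocount,
        )
        top, full = _scoring.rank_pairs(scores, top_k=opt.top_k)
        return SynergyResults(
            model=self, grns=grns, baseline=base, modules_by_sample=per_sample,
            omu_system=system, vectors=vectors, tree=tree, balance_node=node,
            ilrs=ilrs, linear_model=linmod, scores=scores, top=top, ranking=full,
        )


@dataclass
class SynergyResults:
    """Fitted pipeline state: estimates, diagnostics and the ranking."""

    model: SynergyModel
    grns: dict
    baseline: object
    modules_by_sample: dict
    omu_system: object
    vectors: dict
    tree: object
    balance_node: object
    ilrs: dict
    linear_model: object
    scores: pd.DataFrame
    top: pd.DataFrame
    ranking: pd.DataFrame

    @property
    def slope(self) -> float:
        return self.linear_model.slope

    @property
    def intercept(self) -> float:
        return self.linear_model.intercept

    @property
    def pearson_r(self) -> float:
        return self.linear_model.pearson_r

    @property
    def rsquared(self) -> float:
        return self.linear_model.r_squared

    def summary(self) -> str:
        lm = self.linear_model
        n_mod = sum(len(m) for m in self.modules_by_sample.values())
        counts = [len(m) for m in self.modules_by_sample.values()]
        lines = [
            "Two-drug synergy prioritization",
            "=" * 47,
            f"conditions (drugs):            {len(self.vectors):>10d}",
            f"differential modules:          {n_mod:>10d}"
            f"  (per drug {min(counts)}..{max(counts)})",
            f"OMUs in system:                {len(self.omu_system):>10d}",
            f"balance point (node id):       {lm.node_id:>10d}",
            f"  centroid mean GRmax:         {self.balance_node.centroid:>10.3f}",
            f"ILR ~ GRmax Pearson r:         {lm.pearson_r:>10.3f}",
            f"R-squared:                     {lm.r_squared:>10.3f}",
            f"slope / intercept:        {lm.slope:>10.3f} / {lm.intercept:.3f}",
            f"scored pairs:                  {len(self.ranking):>10d}",
            f"top candidates reported:       {len(self.top):>10d}",
        ]
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Scatter of per-drug ILR balance vs GRmax with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = np.asarray(list(self.ilrs.values()))
        ys = np.asarray([self.model.gr_table[s] for s in self.ilrs])
        ax.scatter(xs, ys, s=18)
        grid = np.linspace(xs.min(), xs.max(), 50)
        ax.plot(grid, self.linear_model.intercept + self.linear_model.slope * grid,
                color="firebrick")
        ax.set_xlabel("ILR balance")
        ax.set_ylabel("GRmax")
        ax.set_title(f"r = {self.pearson_r:.3f}, R$^2$ = {self.rsquared:.3f}")
        return ax

    def plot_dgis_distribution(self, ax=None, bins: int = 40):
        """Histogram of DGIS over all scored pairs (mode expected at zero)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.ranking["dgis"], bins=bins)
        ax.set_xlabel("DGIS")
        ax.set_ylabel("pairs")
        return ax
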