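"""Seeded synthetic studies for the full pipeline.

A study emulates the input bundle the pipeline consumes in the real setting
(single-profile transcriptomics per drug, curated regulatory priors, and 6x6
combination dose-response screens) with planted ground truth:

* a block-structured TF->gene prior and TF-TF interaction network with
  ``n_planted_modules`` co-regulated blocks; the first two blocks are
  "death-associated",
* one expression profile per condition in which each drug up-regulates the
  death blocks with a drug-specific magnitude (split between the two death
  blocks) plus one neutral block; only a random subset of a block's genes
  responds, with gene-specific loadings, so perturbations are heterogeneous
  within a block the way real regulons are,
* GRmax assigned as a decreasing linear function of the drug's total
  death-block perturbation plus Gaussian noise, clipped to [-1, 1],
* combination dose-response matrices following the independence (Bliss)
  expectation of the drugs' 4PL monotherapy curves, plus the configured
  interaction strength for planted synergistic pairs.

Planted transcriptomic synergy means *complementary* death programs: the two
drugs of a synergy pair split their death perturbation 90/10 toward opposite
death blocks, so their combined (element-wise max) OMU vector covers both
death programs at full strength while ordinary drugs (split near 50/50) gain
little from combination.

All randomness flows from the single integer ``seed`` through per-component
substreams, so identical configurations are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .doseresponse import DoseResponseMatrix, four_pl
from .io_formats import EdgeList, ExpressionMatrix, GRTable


@dataclass
class StudyConfig:
    n_drugs: int = 20
    n_tfs: int = 30
    n_genes: int = 200
    n_planted_modules: int = 6
    grmax_range: tuple[float, float] = (-0.95, 0.95)
    synergy_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    noise_sd: float = 0.1
    dr_noise_sd: float = 0.005
    seed: int = 1

    # block wiring densities
    prior_p_in: float = 0.85
    prior_p_out: float = 0.04
    ppi_p_in: float = 0.6
    ppi_p_out: float = 0.05
    # expression perturbation scales
    death_amplitude: float = 2.5
    neutral_amplitude_range: tuple[float, float] = (0.4, 1.2)
    neutral_block_prob: float = 0.75
    responsive_fraction: float = 0.7

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.n_tfs, self.n_genes, self.n_planted_modules) < 1:
            raise ValueError("all counts must be positive")
        if self.n_planted_modules < 3:
            raise ValueError("need >= 3 planted blocks (2 death + >= 1 neutral)")
        drugs = set(self.drug_ids())
        for d1, d2, strength in self.synergy_pairs:
            if d1 not in drugs or d2 not in drugs:
                raise ValueError(f"synergy pair ({d1}, {d2}) names unknown drugs")

    def drug_ids(self) -> list[str]:
        width = len(str(self.n_drugs))
        return [f"drug{str(i + 1).zfill(width)}" for i in range(self.n_drugs)]

    @property
    def control_id(self) -> str:
        return "control"

    def _rng(self, component: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, component])


def _blocks(cfg: StudyConfig) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Deterministic split of TFs and genes into planted blocks."""
    tf_blocks = np.array_split(np.arange(cfg.n_tfs), cfg.n_planted_modules)
    gene_blocks = np.array_split(np.arange(cfg.n_genes), cfg.n_planted_modules)
    return tf_blocks, gene_blocks


def _tf_name(i: int, cfg: StudyConfig) -> str:
    return f"TF{str(i + 1).zfill(len(str(cfg.n_tfs)))}"


def _gene_name(i: int, cfg: StudyConfig) -> str:
    return f"G{str(i + 1).zfill(len(str(cfg.n_genes)))}"


def generate_network_priors(cfg: StudyConfig) -> tuple[EdgeList, EdgeList]:
    """Block-structured TF->gene prior and TF-TF interaction network."""
    rng = cfg._rng(1)
    tf_blocks, gene_blocks = _blocks(cfg)
    tf_block = np.empty(cfg.n_tfs, dtype=int)
    gene_block = np.empty(cfg.n_genes, dtype=int)
    for b, (tfs, genes) in enumerate(zip(tf_blocks, gene_blocks)):
        tf_block[tfs] = b
        gene_block[genes] = b

    prior_records = []
    for t in range(cfg.n_tfs):
        for g in range(cfg.n_genes):
            p = cfg.prior_p_in if tf_block[t] == gene_block[g] else cfg.prior_p_out
            if rng.random() < p:
                prior_records.append((_tf_name(t, cfg), _gene_name(g, cfg), 1.0))

    ppi_records = []
    for t1 in range(cfg.n_tfs):
        for t2 in range(t1 + 1, cfg.n_tfs):
            within = tf_block[t1] == tf_block[t2]
            p = cfg.ppi_p_in if within else cfg.ppi_p_out
            if rng.random() < p:
                w = rng.uniform(0.5, 1.0) if within else rng.uniform(0.1, 0.5)
                a, b = _tf_name(t1, cfg), _tf_name(t2, cfg)
                ppi_records.extend([(a, b, float(w)), (b, a, float(w))])
    # every TF must appear in the PPI for intersection mode; tie isolated TFs
    # weakly to another TF of their block (self-loops would be dropped on read)
    present = {s for s, _, _ in ppi_records}
    for t in range(cfg.n_tfs):
        name = _tf_name(t, cfg)
        if name not in present:
            mates = [m for m in tf_blocks[tf_block[t]] if m != t]
            other = _tf_name(int(mates[0]) if len(mates) else (t + 1) % cfg.n_tfs, cfg)
            ppi_records.extend([(name, other, 0.1), (other, name, 0.1)])
            present.update({name, other})
    prior = EdgeList(records=sorted(prior_records))
    ppi = EdgeList(records=sorted(ppi_records), symmetric=True)
    return prior, ppi


@dataclass
class DrugEffects:
    """Planted per-drug ground truth shared by expression and dose-response."""

    total_death: dict[str, float]                    # e_d in (0, 1]
    death_split: dict[str, float]                    # share of e_d on death block 0
    neutral_amplitude: dict[tuple[str, int], float]  # (drug, block) -> amplitude


def drug_effects(cfg: StudyConfig) -> DrugEffects:
    rng = cfg._rng(2)
    drugs = cfg.drug_ids()
    e = dict(zip(drugs, rng.uniform(0.15, 1.0, size=cfg.n_drugs)))
    split = dict(zip(drugs, rng.uniform(0.35, 0.65, size=cfg.n_drugs)))
    lo, hi = cfg.neutral_amplitude_range
    neutral: dict[tuple[str, int], float] = {}
    for drug in drugs:
        for block in range(2, cfg.n_planted_modules):
            if rng.random() < cfg.neutral_block_prob:
                neutral[(drug, block)] = float(rng.uniform(lo, hi))
    # planted synergy pairs: complementary death programs whose split shift
    # scales with the interaction strength, on drugs with substantial death
    # activity (a synergistic combination needs two active, complementary
    # partners to show super-additive growth inhibition)
    for d1, d2, strength in cfg.synergy_pairs:
        shift = min(0.5, 2.0 * strength)
        split[d1], split[d2] = 0.5 + shift, 0.5 - shift
        e[d1] = max(e[d1], 0.6)
        e[d2] = max(e[d2], 0.6)
    return DrugEffects(total_death=e, death_split=split, neutral_amplitude=neutral)


def generate_expression_and_gr(
    cfg: StudyConfig, priors: tuple[EdgeList, EdgeList] | None = None
) -> tuple[ExpressionMatrix, GRTable]:
    """Control plus per-drug expression profiles, and the matching GR table."""
    rng = cfg._rng(3)
    effects = drug_effects(cfg)
    _, gene_blocks = _blocks(cfg)
    drugs = cfg.drug_ids()

    baseline = rng.normal(8.0, 0.5, size=cfg.n_genes)
    loading = rng.uniform(0.5, 1.5, size=cfg.n_genes)  # gene-specific response

    sample_ids = [cfg.control_id] + drugs
    x = np.empty((cfg.n_genes, len(sample_ids)))
    x[:, 0] = baseline + rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)

    gr_lo, gr_hi = cfg.grmax_range
    gr: dict[str, float] = {}
    for col, drug in enumerate(drugs, start=1):
        profile = baseline.copy()
        e_d = effects.total_death[drug]
        alpha = effects.death_split[drug]
        per_block = {
            0: cfg.death_amplitude * e_d * alpha,
            1: cfg.death_amplitude * e_d * (1.0 - alpha),
        }
        for block in range(2, cfg.n_planted_modules):
            amp = effects.neutral_amplitude.get((drug, block))
            if amp is not None:
                per_block[block] = amp
        for block, amplitude in per_block.items():
            genes = gene_blocks[block]
            responsive = rng.random(len(genes)) < cfg.responsive_fraction
            profile[genes[responsive]] += amplitude * loading[genes[responsive]]
        x[:, col] = profile + rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)
        raw = gr_hi - (gr_hi - gr_lo) * e_d + rng.normal(0.0, cfg.noise_sd)
        gr[drug] = float(np.clip(raw, -1.0, 1.0))

    expr = ExpressionMatrix(
        gene_ids=[_gene_name(i, cfg) for i in range(cfg.n_genes)],
        sample_ids=sample_ids,
        values=x,
    )
    return expr, GRTable(records=gr)


def _monotherapy_params(cfg: StudyConfig, gr: GRTable):
    """Per-drug 4PL parameters whose plateau matches the drug's GRmax."""
    rng = cfg._rng(4)
    params = {}
    for drug in cfg.drug_ids():
        e_max = float(np.clip((1.0 - gr[drug]) / 2.0, 0.0, 1.0))
        ec50 = float(rng.lognormal(mean=0.0, sigma=0.5))  # ~1 uM scale
        slope = float(rng.uniform(0.8, 2.0))
        params[drug] = (e_max, ec50, slope)
    return params


def generate_dose_response(
    cfg: StudyConfig,
    gr: GRTable,
    pairs: list[tuple[str, str]] | None = None,
) -> dict[tuple[str, str], DoseResponseMatrix]:
    """6x6 combination matrices (zero-dose margins + Bliss interior).

    Interior cells follow y1 + y2 - y1*y2 plus the planted interaction
    strength for configured synergy pairs (zero otherwise) plus Gaussian
    noise, clipped to [0, 1].  ``pairs=None`` generates every unordered pair.
    """
    rng = cfg._rng(5)
    params = _monotherapy_params(cfg, gr)
    interaction = {tuple(sorted((d1, d2))): s for d1, d2, s in cfg.synergy_pairs}
    drugs = cfg.drug_ids()
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(drugs) for b in drugs[i + 1:]]

    out: dict[tuple[str, str], DoseResponseMatrix] = {}
    for d1, d2 in pairs:
        key = tuple(sorted((d1, d2)))
        e1, c1, h1 = params[key[0]]
        e2, c2, h2 = params[key[1]]
        doses1 = np.concatenate([[0.0], c1 * np.logspace(-1.5, 1.5, 5)])
        doses2 = np.concatenate([[0.0], c2 * np.logspace(-1.5, 1.5, 5)])
        y1 = four_pl(doses1, 0.0, e1, c1, h1)
        y2 = four_pl(doses2, 0.0, e2, c2, h2)
        resp = y1[:, None] + y2[None, :] - y1[:, None] * y2[None, :]
        resp[1:, 1:] += interaction.get(key, 0.0)
        if cfg.dr_noise_sd > 0:
            resp = resp + rng.normal(0.0, cfg.dr_noise_sd, size=resp.shape)
        resp[0, 0] = 0.0
        out[key] = DoseResponseMatrix(
            drug1=key[0], drug2=key[1], conc1=doses1, conc2=doses2,
            responses=np.clip(resp, 0.0, 1.0),
        )
    return out


@dataclass
class SyntheticStudy:
    config: StudyConfig
    prior: EdgeList
    ppi: EdgeList
    expression: ExpressionMatrix
    gr_table: GRTable
    effects: DrugEffects


def generate_study(cfg: StudyConfig) -> SyntheticStudy:
    """All pipeline inputs for one seeded study (dose-response on demand)."""
    prior, ppi = generate_network_priors(cfg)
    expr, gr = generate_expression_and_gr(cfg, (prior, ppi))
    return SyntheticStudy(
        config=cfg, prior=prior, ppi=ppi, expression=expr, gr_table=gr,
        effects=drug_effects(cfg),
    )
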