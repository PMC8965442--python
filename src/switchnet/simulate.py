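"""Synthetic case/control expression matrices with planted network structure.

The generator emulates the structure the switch-gene pipeline assumes in real
transcriptomes:

* ``n_modules`` groups of co-expressed genes, each driven by a per-sample
  latent factor (one factor per module, standard normal across samples);
* a case-vs-control shift of ``de_log2fc`` log2 units on every structured
  gene, so the differential filter has a planted positive set;
* ``n_switch`` switch genes that load *negatively* on the average of two or
  more module factors and carry the opposite case shift, guaranteeing
  anti-correlation with the members of the modules they span (the defining
  property of a fight-club hub) while remaining differentially expressed;
* unstructured noise genes with no group shift, which the filter should drop.

Everything is deterministic given ``seed`` and the full ground truth (module
labels, switch genes, differentially expressed genes) is returned alongside
the matrix so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate", "fold_change_histogram"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions for one synthetic dataset.

    Defaults are the strong-signal benchmark configuration used throughout
    the test-suite: 4 modules x 25 genes, 5 switch genes, 10+10 samples,
    loading 0.9, noise sd 0.3, case shift 1.5 log2 units.
    """

    n_modules: int = 4
    genes_per_module: int = 25
    n_switch: int = 5
    n_noise_genes: int = 50
    samples_per_group: int = 10
    loading: float = 0.9
    noise_sd: float = 0.3
    de_log2fc: float = 1.5
    modules_per_switch: int = 2
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules < 1 or self.genes_per_module < 1:
            raise ValueError("n_modules and genes_per_module must be >= 1")
        if self.n_switch < 0 or self.n_noise_genes < 0:
            raise ValueError("n_switch and n_noise_genes must be >= 0")
        if self.samples_per_group < 3:
            raise ValueError("samples_per_group must be >= 3")
        if not 0 < self.loading <= 1:
            raise ValueError("loading must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_switch > 0 and self.n_modules < 2:
            raise ValueError("switch genes span >= 2 modules; need n_modules >= 2")
        if self.n_switch > 0 and not 2 <= self.modules_per_switch <= self.n_modules:
            raise ValueError("modules_per_switch must be in [2, n_modules]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted labels for one generated matrix."""

    module_of: dict[str, str]                  # gene -> "M1".."Mk" | "switch" | "noise"
    switch_genes: frozenset[str]
    de_genes: frozenset[str]                   # all structured genes (members + switch)
    switch_modules: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def members_of(self, module: int) -> list[str]:
        return [g for g, m in self.module_of.items() if m == f"M{module}"]


def generate(config: SyntheticConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw one expression matrix plus its ground truth.

    Per sample, module ``m`` has a latent factor f_m ~ N(0, 1).  A member of
    module ``m`` is ``loading * f_m + noise_sd * eps + de_log2fc * case``; a
    switch gene spanning modules ``S`` is
    ``-loading * mean(f_S) + noise_sd * eps - de_log2fc * case``; noise genes
    are pure measurement noise ``noise_sd * eps`` with no shift, so in the
    noiseless limit the differential filter retains exactly the structured
    genes.  A per-gene baseline level around ``baseline_mean`` puts
    everything on a realistic log2 scale.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_per = cfg.samples_per_group
    samples = [f"ctrl_{i + 1:02d}" for i in range(n_per)] + \
              [f"case_{i + 1:02d}" for i in range(n_per)]
    case_ind = np.r_[np.zeros(n_per), np.ones(n_per)]
    groups = pd.Series(["control"] * n_per + ["case"] * n_per, index=samples)

    # centre each factor within both groups: the module structure is then
    # exactly orthogonal to the disease axis, so the planted fold change of
    # every structured gene is exactly +-de_log2fc in the noiseless limit
    # and no module can be lost to chance factor/group confounding
    factors = rng.standard_normal((cfg.n_modules, 2 * n_per))
    factors[:, :n_per] -= factors[:, :n_per].mean(axis=1, keepdims=True)
    factors[:, n_per:] -= factors[:, n_per:].mean(axis=1, keepdims=True)

    rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    module_of: dict[str, str] = {}
    switch_modules: dict[str, tuple[int, ...]] = {}

    for m in range(cfg.n_modules):
        for g in range(cfg.genes_per_module):
            gid = f"M{m + 1}_{g + 1:03d}"
            profile = (cfg.loading * factors[m]
                       + cfg.noise_sd * rng.standard_normal(2 * n_per)
                       + cfg.de_log2fc * case_ind)
            rows.append(profile)
            gene_ids.append(gid)
            module_of[gid] = f"M{m + 1}"

    for s in range(cfg.n_switch):
        gid = f"SW_{s + 1:02d}"
        span = tuple(sorted(rng.choice(cfg.n_modules, size=cfg.modules_per_switch,
                                       replace=False) + 1))
        profile = (-cfg.loading * factors[[m - 1 for m in span]].mean(axis=0)
                   + cfg.noise_sd * rng.standard_normal(2 * n_per)
                   - cfg.de_log2fc * case_ind)
        rows.append(profile)
        gene_ids.append(gid)
        module_of[gid] = "switch"
        switch_modules[gid] = span

    for g in range(cfg.n_noise_genes):
        gid = f"NOISE_{g + 1:03d}"
        rows.append(cfg.noise_sd * rng.standard_normal(2 * n_per))
        gene_ids.append(gid)
        module_of[gid] = "noise"

    baselines = cfg.baseline_mean + cfg.baseline_sd * rng.standard_normal(len(rows))
    values = pd.DataFrame(np.asarray(rows) + baselines[:, None],
                          index=gene_ids, columns=samples)
    expr = ExpressionMatrix(values, groups, log2_scale=True)
    switch = frozenset(switch_modules)
    de = frozenset(g for g, m in module_of.items() if m != "noise")
    return expr, SyntheticTruth(module_of, switch, de, switch_modules)


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """The same conditions under a different random seed."""
    return replace(config, seed=int(seed))


def fold_change_histogram(expr: ExpressionMatrix, bins: int = 30
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-gene log2 fold changes (counts, bin_edges).

    Total count equals the number of genes; this is the data behind the
    retained/discarded fold-change bar plots.
    """
    from .diffexp import log2_fold_changes

    lfc = log2_fold_changes(expr)
    counts, edges = np.histogram(lfc.to_numpy(), bins=bins)
    return counts, edges
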