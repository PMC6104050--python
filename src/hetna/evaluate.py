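"""Alignment scoring against ground truth and the noise-sweep experiment.

``run_sweep`` drives the full synthetic protocol: generate a network,
color it, rewire it at each noise level, build signatures and a
similarity matrix per scenario, align, and score node correctness
against the known identity mapping — all reproducibly derived from a
single master seed.  ``rank_summary`` turns the resulting tidy table
into the rank-frequency summaries used for reporting (ties share the
best rank; the 100% noise level is excluded by default).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .aligners import ObjectiveConfig, magna_align, sana_align, wave_align
from .graphlets import count_gdv, count_ncgdv
from .netmodel import Alignment, ColoredNetwork, TrueMapping
from .similarity import build_similarity
from .synth import assign_colors_random, generate_geo, generate_sf, rewire_noise

__all__ = [
    "node_correctness",
    "SweepConfig",
    "run_sweep",
    "rank_summary",
    "select_best_scenarios",
    "SCENARIOS",
]

SCENARIOS = ("HomNC-HomEC", "HetNC-HomEC", "HomNC-HetEC", "HetNC-HetEC")


def node_correctness(alignment: Union[Alignment, Dict[str, str]],
                     truth: TrueMapping) -> float:
    """Percentage of aligned pairs agreeing with the true mapping."""
    mapping = alignment.mapping if isinstance(alignment, Alignment) else alignment
    if set(mapping) != set(truth.pairs):
        raise ValueError("alignment and true mapping cover different source nodes")
    if not mapping:
        raise ValueError("empty alignment")
    hits = sum(1 for u, v in mapping.items() if truth.pairs[u] == v)
    return 100.0 * hits / len(mapping)


@dataclass
class SweepConfig:
    """Factor grid and budgets for the synthetic noise-robustness sweep."""

    models: Sequence[str] = ("geo", "sf")
    methods: Sequence[str] = ("wave", "sana")
    scenarios: Sequence[str] = ("HetNC-HetEC",)
    ks: Sequence[int] = (1, 2, 4)
    noise_levels: Sequence[float] = (0.0, 0.25, 0.5)
    replicates: int = 3
    n: int = 300
    m: int = 1800
    master_seed: int = 0
    alpha: float = 0.5
    max_graphlet_size: int = 5
    reduction: str = "pca"
    variance_target: float = 0.9
    sana_budget: int = 2_000_000
    magna_population: int = 200
    magna_generations: int = 100

    def __post_init__(self):
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ValueError(f"unknown scenario {s!r}")
        for mth in self.methods:
            if mth not in ("wave", "sana", "magna"):
                raise ValueError(f"unknown method {mth!r}")
        for mdl in self.models:
            if mdl not in ("geo", "sf"):
                raise ValueError(f"unknown model {mdl!r}")


_GENERATORS = {"geo": generate_geo, "sf": generate_sf}


def _scenario_parts(scenario: str):
    nc, ec = scenario.split("-")
    return nc == "HetNC", "hets3" if ec == "HetEC" else "homs3"


def run_sweep(cfg: SweepConfig, progress=None) -> pd.DataFrame:
    """Run the full factor grid; returns one row per (cell, replicate)."""
    rows: List[dict] = []
    seed_counter = 0

    def next_seed() -> int:
        nonlocal seed_counter
        seed_counter += 1
        return cfg.master_seed * 1_000_003 + seed_counter

    for model in cfg.models:
        for rep in range(cfg.replicates):
            base = _GENERATORS[model](cfg.n, cfg.m, next_seed())
            noisy_by_level = {
                lvl: rewire_noise(base, lvl, next_seed())
                for lvl in cfg.noise_levels
            }
            for k in cfg.ks:
                colored = assign_colors_random(base, k, next_seed())
                sig_het_g = count_ncgdv(colored, max_size=cfg.max_graphlet_size)
                sig_hom_g = count_gdv(colored, max_size=cfg.max_graphlet_size)
                for lvl in cfg.noise_levels:
                    noisy_topology, truth = noisy_by_level[lvl]
                    noisy = noisy_topology.with_node_colors(colored.node_color)
                    sig_het_h = count_ncgdv(noisy, colors=colored.colors,
                                            max_size=cfg.max_graphlet_size)
                    sig_hom_h = count_gdv(noisy, max_size=cfg.max_graphlet_size)
                    sims = {}
                    for method in cfg.methods:
                        cache: Dict[tuple, Alignment] = {}
                        for scenario in cfg.scenarios:
                            het_nc, ec_measure = _scenario_parts(scenario)
                            if het_nc not in sims:
                                sims[het_nc] = build_similarity(
                                    sig_het_g if het_nc else sig_hom_g,
                                    sig_het_h if het_nc else sig_hom_h,
                                    reduction=cfg.reduction,
                                    variance_target=cfg.variance_target)
                            sim = sims[het_nc]
                            objective = ObjectiveConfig(alpha=cfg.alpha,
                                                        ec_measure=ec_measure)
                            seed = next_seed()
                            # WAVE ignores EC: reuse the alignment across EC variants
                            cache_key = (method, het_nc) if method == "wave" \
                                else (method, het_nc, ec_measure)
                            t_start = time.perf_counter()
                            if cache_key in cache:
                                aln = cache[cache_key]
                            elif method == "wave":
                                aln = wave_align(colored, noisy, sim)
                            elif method == "sana":
                                aln = sana_align(colored, noisy, sim,
                                                 objective=objective,
                                                 budget=cfg.sana_budget,
                                                 seed=seed)
                            else:
                                aln = magna_align(colored, noisy, sim,
                                                  objective=objective,
                                                  population=cfg.magna_population,
                                                  generations=cfg.magna_generations,
                                                  seed=seed)
                            cache[cache_key] = aln
                            runtime = time.perf_counter() - t_start
                            row = {
                                "model": model, "method": method,
                                "scenario": scenario, "k": k, "noise": lvl,
                                "replicate": rep, "seed": seed,
                                "node_correctness": node_correctness(aln, truth),
                                "objective": aln.objective,
                                "runtime_s": runtime,
                            }
                            rows.append(row)
                            if progress is not None:
                                progress(row)
    return pd.DataFrame(rows)


def select_best_scenarios(result: pd.DataFrame,
                          scenarios: Sequence[str]) -> pd.DataFrame:
    """Keep, per cell, the best-scoring row among the given scenarios."""
    sub = result[result["scenario"].isin(list(scenarios))]
    keys = ["model", "method", "k", "noise", "replicate"]
    idx = sub.groupby(keys)["node_correctness"].idxmax()
    out = sub.loc[idx].copy()
    out["scenario"] = "best-of-" + "/".join(scenarios)
    return out.reset_index(drop=True)


def rank_summary(result: pd.DataFrame, group_by: str = "k",
                 exclude_full_noise: bool = True) -> pd.DataFrame:
    """Rank-frequency table: how often each level of ``group_by`` ranks 1st, 2nd, ...

    A *case* is a unique combination of every other factor (replicates
    averaged first); within a case levels are ranked by mean node
    correctness, ties sharing the best applicable rank.  Values are
    percentages of cases; each level's row sums to 100.
    """
    if result.empty:
        raise ValueError("empty result table")
    df = result.copy()
    if exclude_full_noise and "noise" in df.columns:
        df = df[df["noise"] < 1.0]
    factors = [c for c in ("model", "method", "scenario", "k", "noise")
               if c in df.columns and c != group_by]
    mean = (df.groupby(factors + [group_by], as_index=False)["node_correctness"]
              .mean())
    levels = sorted(mean[group_by].unique())
    n_levels = len(levels)
    freq = {lvl: np.zeros(n_levels) for lvl in levels}
    cases = list(mean.groupby(factors)) if factors else [((), mean)]
    for _, case in cases:
        scores = case.set_index(group_by)["node_correctness"]
        for lvl in scores.index:
            rank = int((scores > scores[lvl] + 1e-12).sum())  # ties share best rank
            freq[lvl][rank] += 1
    n_cases = len(cases)
    table = pd.DataFrame(
        {f"rank{r + 1}": [100.0 * freq[lvl][r] / n_cases for lvl in levels]
         for r in range(n_levels)},
        index=pd.Index(levels, name=group_by))
    return table
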