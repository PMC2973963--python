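"""High-level pipelines: search one dataset, or run a whole power study.

These functions wire the modules together the way the command-line interface
does: simulate (or load) a dataset, run the restarted GA search, rank the
factor combinations, and score the result against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import GenotypeMatrix, PhenotypeLabels
from .evaluate import (
    IdentificationOutcome,
    RankedCallSet,
    fdr_at,
    power,
    success_from_calls,
    tpr_at,
)
from .fitness import EnsembleConfig
from .ga import BestSubsetRecord, GAConfig, default_ga_config, run_restarts
from .ranking import CombinationScore, enumerate_combinations
from .simulate import SimulatedDataset, make_replicates


@dataclass
class SearchResult:
    records: list[BestSubsetRecord]
    scores: list[CombinationScore]


def identify_interactions(
    data: GenotypeMatrix,
    labels: PhenotypeLabels,
    ga_config: GAConfig | None = None,
    ens_config: EnsembleConfig | None = None,
    k_min: int = 2,
    k_max: int = 3,
) -> SearchResult:
    """Restarted GA search plus combinatorial ranking on one dataset."""
    records = run_restarts(data, labels, ga_config, ens_config)
    scores = enumerate_combinations(
        [r.factor_ids for r in records], k_min=k_min, k_max=k_max
    )
    return SearchResult(records, scores)


def ranked_calls_for_replicate(
    ds: SimulatedDataset, result: SearchResult
) -> RankedCallSet:
    return RankedCallSet(tuple(result.scores), ds.functional_pair)


@dataclass
class PowerStudy:
    outcome: IdentificationOutcome
    replicates: list[RankedCallSet]

    @property
    def power(self) -> float:
        return power(self.outcome)

    def fdr(self, cutoff, mode: str = "frequency") -> float:
        return fdr_at(self.replicates, cutoff, mode)

    def tpr(self, cutoff, mode: str = "frequency") -> float:
        return tpr_at(self.replicates, cutoff, mode)


def estimate_power(
    design: str | dict,
    n_replicates: int,
    base_seed: int = 0,
    ga_config: GAConfig | None = None,
    ens_config: EnsembleConfig | None = None,
    restarts: int = 30,
    algorithm: str = "GE",
) -> PowerStudy:
    """Simulate replicates of a design and measure identification power.

    Each replicate is searched with its own master seed (derived from
    ``base_seed``) and succeeds when the true functional pair is the
    top-ranked pair of the frequency ranking.
    """
    datasets = make_replicates(design, n_replicates, base_seed)
    calls: list[RankedCallSet] = []
    successes = np.zeros(n_replicates, dtype=bool)
    for i, ds in enumerate(datasets):
        if ga_config is None:
            cfg = default_ga_config(
                ds.genotypes.n_factors, restarts=restarts, master_seed=ds.seed * 1000
            )
        else:
            cfg = cfg_with_seed(ga_config, ds.seed * 1000)
        if ens_config is None:
            ens = EnsembleConfig(protocol_seed=ds.seed)
        else:
            ens = ens_config
        result = identify_interactions(ds.genotypes, ds.labels, cfg, ens)
        rc = ranked_calls_for_replicate(ds, result)
        calls.append(rc)
        successes[i] = success_from_calls(rc)
    return PowerStudy(IdentificationOutcome(algorithm, successes), calls)


def cfg_with_seed(cfg: GAConfig, master_seed: int) -> GAConfig:
    from dataclasses import replace

    return replace(cfg, master_seed=master_seed)
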