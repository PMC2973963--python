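"""Two-locus epistasis simulator for case-control power studies.

Generates datasets in which a single pair of functional SNPs carries a purely
epistatic effect (no marginal effect at either locus) at a target
heritability, embedded among independent noise SNPs — the standard design for
benchmarking gene-gene interaction detectors on 200-sample case-control data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import CASE, CONTROL, SNP, GenotypeMatrix, PhenotypeLabels, write_genotype_table


@dataclass(frozen=True)
class PenetranceModel:
    """A two-locus disease model: 3x3 penetrance table plus allele frequencies.

    ``table[i, j]`` is P(disease | genotype i at locus A, genotype j at
    locus B) with codes 0/1/2 = aa/Aa/AA.  Prevalence K and heritability h2
    (penetrance-scale: genetic variance over K(1-K)) are derived quantities.
    """

    maf_a: float
    maf_b: float
    table: np.ndarray

    def __post_init__(self) -> None:
        table = np.asarray(self.table, dtype=float)
        object.__setattr__(self, "table", table)
        if table.shape != (3, 3):
            raise ValueError("penetrance table must be 3x3")
        if (table < 0).any() or (table > 1).any():
            raise ValueError("penetrances must lie in [0, 1]")
        for maf in (self.maf_a, self.maf_b):
            if not 0.0 < maf <= 0.5:
                raise ValueError("minor-allele frequencies must be in (0, 0.5]")

    @property
    def prevalence(self) -> float:
        return prevalence(self)

    @property
    def heritability(self) -> float:
        return heritability(self)


def genotype_freqs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities (P(aa), P(Aa), P(AA)).

    Code 2 = AA is the major homozygote, so P(aa) = maf**2.
    """
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    q = maf
    return np.array([q * q, 2 * q * (1 - q), (1 - q) ** 2])


def _joint_genotype_probs(model: PenetranceModel) -> np.ndarray:
    pa = genotype_freqs(model.maf_a)
    pb = genotype_freqs(model.maf_b)
    return np.outer(pa, pb)


def prevalence(model: PenetranceModel) -> float:
    """Population disease probability K = sum_ij p_i p_j f_ij under HWE."""
    return float((_joint_genotype_probs(model) * model.table).sum())


def heritability(model: PenetranceModel) -> float:
    """Penetrance-scale heritability h2 = sum p_i p_j (f_ij - K)^2 / (K(1-K))."""
    k = prevalence(model)
    if not 0.0 < k < 1.0:
        raise ValueError("prevalence must be strictly between 0 and 1")
    var = float((_joint_genotype_probs(model) * (model.table - k) ** 2).sum())
    return var / (k * (1 - k))


def marginal_penetrances(model: PenetranceModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-genotype marginal penetrance at each locus (no-main-effect check)."""
    pa = genotype_freqs(model.maf_a)
    pb = genotype_freqs(model.maf_b)
    return model.table @ pb, model.table.T @ pa


def find_penetrance_table(
    h2_target: float,
    maf: float = 0.2,
    seed: int = 0,
    tol: float = 1e-3,
    max_iter: int = 20_000,
    maf_b: float | None = None,
) -> PenetranceModel:
    """Search for a purely epistatic penetrance table with a given heritability.

    Seeded random search: each iteration draws a random 3x3 deviation matrix,
    projects it onto the subspace with zero HWE-weighted row and column means
    (so neither locus has any marginal effect, exactly), draws a prevalence K,
    and rescales the deviation so the model's heritability equals
    ``h2_target`` analytically.  The draw is accepted if all penetrances land
    in [0, 1].  Deterministic given ``seed``; raises if no feasible table is
    found within ``max_iter`` draws.
    """
    if not 0.0 < h2_target < 1.0:
        raise ValueError("h2_target must be in (0, 1)")
    maf_b = maf if maf_b is None else maf_b
    pa = genotype_freqs(maf)
    pb = genotype_freqs(maf_b)
    rng = np.random.default_rng(seed)
    for _ in range(max_iter):
        z = rng.normal(size=(3, 3))
        # weighted double-centering: rows vs p_b, columns vs p_a
        r = z @ pb
        c = pa @ z
        m = float(pa @ z @ pb)
        u = z - r[:, None] - c[None, :] + m
        v = float((np.outer(pa, pb) * u**2).sum())
        if v < 1e-12:
            continue
        k = rng.uniform(0.05, 0.5)
        scale = np.sqrt(h2_target * k * (1 - k) / v)
        table = k + scale * u
        if (table < 0).any() or (table > 1).any():
            continue
        model = PenetranceModel(maf, maf_b, table)
        if abs(model.heritability - h2_target) <= tol:
            return model
    raise RuntimeError(
        f"no penetrance table with h2={h2_target} at maf={maf} "
        f"found in {max_iter} iterations"
    )


@dataclass(frozen=True)
class SimulatedDataset:
    genotypes: GenotypeMatrix
    labels: PhenotypeLabels
    functional_indices: tuple[int, int]
    model: PenetranceModel
    seed: int

    @property
    def functional_ids(self) -> tuple[str, str]:
        i, j = self.functional_indices
        return (self.genotypes.factor_ids[i], self.genotypes.factor_ids[j])

    @property
    def functional_pair(self) -> tuple[str, str]:
        return tuple(sorted(self.functional_ids))  # type: ignore[return-value]


def simulate_dataset(
    model: PenetranceModel,
    n_case: int,
    n_control: int,
    n_noise_snps: int,
    noise_maf: float | tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> SimulatedDataset:
    """Draw a case-control dataset with the functional pair embedded.

    Functional genotype pairs are sampled from the exact conditional
    distribution P(g_a, g_b | status) — proportional to p_a p_b f for cases
    and p_a p_b (1 - f) for controls — by inverse-CDF over the nine genotype
    cells.  Noise SNPs are independent HWE draws at ``noise_maf`` (a scalar,
    or a range sampled uniformly per SNP).  The two functional columns are
    placed at seeded-random positions recorded in ``functional_indices``.
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("sample counts must be positive")
    k = model.prevalence
    if not 0.0 < k < 1.0:
        raise ValueError("model prevalence must be in (0, 1) to condition on status")
    rng = np.random.default_rng(seed)
    joint = _joint_genotype_probs(model)
    p_case = (joint * model.table).ravel() / k
    p_control = (joint * (1 - model.table)).ravel() / (1 - k)

    m = n_case + n_control
    labels = np.concatenate(
        [np.full(n_case, CASE, dtype=np.int8), np.full(n_control, CONTROL, dtype=np.int8)]
    )
    cells = np.concatenate(
        [
            _inverse_cdf_sample(p_case, n_case, rng),
            _inverse_cdf_sample(p_control, n_control, rng),
        ]
    )
    ga, gb = cells // 3, cells % 3

    n_total = n_noise_snps + 2
    values = np.empty((m, n_total), dtype=np.int16)
    if np.isscalar(noise_maf):
        mafs = np.full(n_noise_snps, float(noise_maf))  # type: ignore[arg-type]
    else:
        lo, hi = noise_maf  # type: ignore[misc]
        mafs = rng.uniform(lo, hi, size=n_noise_snps)
    pos = rng.permutation(n_total)
    fa, fb = int(pos[0]), int(pos[1])
    noise_cols = [int(p) for p in pos[2:]]
    values[:, fa] = ga
    values[:, fb] = gb
    for col, maf in zip(noise_cols, mafs):
        probs = genotype_freqs(float(maf))
        values[:, col] = _inverse_cdf_sample(probs, m, rng)

    ids = [f"snp{j + 1}" for j in range(n_total)]
    gm = GenotypeMatrix(ids, [SNP] * n_total, values)
    return SimulatedDataset(gm, PhenotypeLabels(labels), (fa, fb), model, seed)


def _inverse_cdf_sample(probs: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    cdf = np.cumsum(probs)
    cdf[-1] = 1.0
    return np.searchsorted(cdf, rng.random(n), side="right").astype(np.int16)


# ---------------------------------------------------------------------------
# Named study designs: <balance>_<samples>_<heritability>_<snps>

_BALANCED = (100, 100)
_IMBALANCED = (67, 133)

DESIGNS: dict[str, dict] = {}
for _h in (0.2, 0.1, 0.05):
    for _s in (20, 100):
        DESIGNS[f"balanced_200_{_h}_{_s}"] = {
            "n_case": _BALANCED[0],
            "n_control": _BALANCED[1],
            "n_snps": _s,
            "heritability": _h,
        }
    DESIGNS[f"imbalanced_200_{_h}_20"] = {
        "n_case": _IMBALANCED[0],
        "n_control": _IMBALANCED[1],
        "n_snps": 20,
        "heritability": _h,
    }

DEFAULT_FUNCTIONAL_MAF = 0.2


def make_replicates(
    design: str | dict,
    n_replicates: int,
    base_seed: int = 0,
    model: PenetranceModel | None = None,
) -> list[SimulatedDataset]:
    """Generate seeded replicate datasets of one study design.

    ``design`` is a named configuration (see ``DESIGNS``) or an explicit dict
    with keys n_case/n_control/n_snps/heritability.  One penetrance model is
    shared by all replicates of the set (searched with a seed derived from
    ``base_seed`` unless given); replicate i uses seed ``base_seed + i``.
    """
    if isinstance(design, str):
        try:
            params = DESIGNS[design]
        except KeyError:
            raise KeyError(
                f"unknown design {design!r}; valid names: {sorted(DESIGNS)}"
            ) from None
    else:
        params = design
    if model is None:
        model = find_penetrance_table(
            params["heritability"], DEFAULT_FUNCTIONAL_MAF, seed=base_seed
        )
    return [
        simulate_dataset(
            model,
            params["n_case"],
            params["n_control"],
            params["n_snps"] - 2,
            seed=base_seed + i,
        )
        for i in range(n_replicates)
    ]


def write_dataset(ds: SimulatedDataset, path: str | Path) -> None:
    """Write the dataset TSV plus a sidecar .truth.json ground-truth file."""
    path = Path(path)
    write_genotype_table(ds.genotypes, ds.labels, path)
    truth = {
        "functional_ids": list(ds.functional_ids),
        "functional_indices": list(ds.functional_indices),
        "penetrance_table": ds.model.table.tolist(),
        "maf_a": ds.model.maf_a,
        "maf_b": ds.model.maf_b,
        "prevalence": ds.model.prevalence,
        "heritability": ds.model.heritability,
        "seed": ds.seed,
    }
    path.with_suffix(path.suffix + ".truth.json").write_text(
        json.dumps(truth, indent=1)
    )
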