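"""Synthetic inputs with planted ground truth for the SL-prediction pipeline.

Emulates, at desk scale, the data types produced by a yeast chemical-genetic
and SGA campaign centred on chromosome-instability (CIN) genes:

* a gene universe with CIN / essentiality / cancer-ortholog annotation,
* a query x array genetic-interaction screen in which a known set of
  high-degree "hub" array genes carries planted negative interactions with
  CIN query genes,
* replicated colony-size measurements for chemical-sensitivity screening
  (nine replicates per strain x chemical, mirroring triplicate pinning
  passaged in triplicate),
* protein-complex membership tying hubs to essential partner genes, and
* single/double-knockdown proliferation counts following a multiplicative
  null with planted synthetic-lethal (SL) defects on the complex-propagated
  (partner, cancer-ortholog) pairs.

All randomness derives from a single seed; each table draws from its own
deterministically derived sub-stream, so tables are reproducible
individually and jointly.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ConsistencyError

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "simulate_gene_universe",
    "simulate_gi_screen",
    "simulate_chemical_screen",
    "simulate_complexes",
    "simulate_proliferation",
]

# Sub-stream indices: each simulated table owns one child stream of the seed.
_STREAM_UNIVERSE = 0
_STREAM_GI = 1
_STREAM_CHEM = 2
_STREAM_COMPLEX = 3
_STREAM_PROLIF = 4

FUNCTIONAL_GROUPS = (
    "DNA replication and repair",
    "mitotic apparatus",
    "chromatin modification and transcription",
    "RNA processing and transport",
    "polarized secretion and ER",
    "metabolism and stress response",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe a screen of ~2000 essential-gene mutants with a fifth
    of the universe annotated as CIN, ten planted interaction hubs each tied
    to 45 CIN queries, nine colony replicates per strain x chemical, and
    double-knockdown proliferation measured in six replicates.
    """

    n_genes: int = 2000
    cin_fraction: float = 0.2
    n_hubs: int = 10
    hub_cin_degree: int = 45
    background_edge_prob: float = 0.05
    interaction_score_mean: float = -0.35
    score_noise_sd: float = 0.05
    n_chem_replicates: int = 9
    colony_size_mean: float = 100.0
    colony_noise_cv: float = 0.10
    sensitive_growth_ratio: float = 0.4
    n_complexes: int = 5
    complex_size: int = 5
    single_kd_effect_range: tuple[float, float] = (0.6, 0.9)
    planted_defect: float = 0.3
    proliferation_noise_cv: float = 0.05
    n_prolif_replicates: int = 6
    seed: int = 0
    # Plumbing the operations need but that has no single canonical value:
    chemicals: tuple[str, ...] = ("MMS", "HU", "benomyl", "rapamycin")
    sensitive_fraction: float = 0.10
    cancer_fraction: float = 0.25
    essential_fraction: float = 0.40
    prolif_count_mean: float = 1000.0
    n_null_pairs: int = 20

    def __post_init__(self) -> None:
        def _prop(name: str, lo_open: bool = False, hi_open: bool = False):
            v = getattr(self, name)
            lo_ok = v > 0 if lo_open else v >= 0
            hi_ok = v < 1 if hi_open else v <= 1
            if not (lo_ok and hi_ok):
                raise ConfigurationError(f"{name}={v} outside its unit-interval domain")

        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        for name in ("n_hubs", "hub_cin_degree", "n_complexes", "complex_size",
                     "n_null_pairs"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("n_chem_replicates", "n_prolif_replicates"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        _prop("cin_fraction", lo_open=True, hi_open=True)
        _prop("background_edge_prob")
        _prop("sensitive_growth_ratio", lo_open=True, hi_open=True)
        _prop("planted_defect", hi_open=True)
        _prop("sensitive_fraction", lo_open=True, hi_open=True)
        _prop("cancer_fraction", lo_open=True)
        _prop("essential_fraction", lo_open=True)
        if self.interaction_score_mean >= 0:
            raise ConfigurationError("interaction_score_mean must be negative "
                                     "(negative = aggravating)")
        for name in ("score_noise_sd", "colony_noise_cv", "proliferation_noise_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.colony_size_mean <= 0 or self.prolif_count_mean <= 0:
            raise ConfigurationError("mean sizes/counts must be positive")
        lo, hi = self.single_kd_effect_range
        if not (0 < lo <= hi <= 1):
            raise ConfigurationError("single_kd_effect_range must lie within (0, 1]")
        if self.hub_cin_degree > self.n_cin:
            raise ConfigurationError(
                f"hub_cin_degree={self.hub_cin_degree} exceeds the number of "
                f"CIN genes ({self.n_cin})")
        if self.n_hubs + self.n_cin > self.n_genes:
            raise ConfigurationError("not enough non-CIN genes to host the hubs")

    @property
    def n_cin(self) -> int:
        return int(np.rint(self.n_genes * self.cin_fraction))

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic per-table generator derived from the single seed."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator, for downstream evaluation.

    ``sl_pairs`` maps an order-canonical (geneA, geneB) tuple (geneA < geneB)
    to its planted proliferative defect; :meth:`sl_defect` looks a pair up in
    either order.
    """

    hub_genes: frozenset[str]
    planted_edges: frozenset[tuple[str, str]]  # (CIN query, hub array gene)
    sensitive_genes_by_chemical: dict[str, frozenset[str]]
    complexes: dict[str, frozenset[str]] = field(default_factory=dict)
    sl_pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    # bookkeeping used by the simulators
    genes: tuple[str, ...] = ()
    cin_genes: frozenset[str] = frozenset()
    cancer_genes: frozenset[str] = frozenset()
    essential_genes: frozenset[str] = frozenset()
    config_fingerprint: str = ""

    def sl_defect(self, gene_a: str, gene_b: str) -> float:
        """Planted defect for a pair, 0.0 if the pair is not planted SL."""
        return self.sl_pairs.get(_canon_pair(gene_a, gene_b), 0.0)


def _canon_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _fingerprint(config: SimulationConfig) -> str:
    return repr(dataclasses.astuple(config))


def _check_truth(config: SimulationConfig, truth: PlantedTruth) -> None:
    if truth.config_fingerprint != _fingerprint(config):
        raise ConsistencyError(
            "PlantedTruth was generated under a different configuration; "
            "re-run simulate_gene_universe with this config")


def _lognormal_noise(rng: np.random.Generator, mean: np.ndarray,
                     cv: float, size: tuple[int, ...] | int) -> np.ndarray:
    """Multiplicative log-normal noise with expectation exactly *mean*.

    Colony sizes and nuclei counts are positive and right-skewed, which the
    log-normal captures; cv=0 returns the means unchanged.
    """
    if cv == 0:
        return np.broadcast_to(np.asarray(mean, dtype=float), size).copy()
    sigma = np.sqrt(np.log1p(cv ** 2))
    factor = np.exp(rng.normal(-sigma ** 2 / 2.0, sigma, size=size))
    return np.asarray(mean, dtype=float) * factor


# ---------------------------------------------------------------------------
# Gene universe


def simulate_gene_universe(config: SimulationConfig) -> tuple[pd.DataFrame, PlantedTruth]:
    """Build the annotated gene universe and the planted truth skeleton.

    Returns the annotation table (gene, essential, is_cin, is_cancer_ortholog,
    functional_group) and a :class:`PlantedTruth` whose hubs, planted
    interaction edges, and per-chemical sensitive sets are filled in.
    Complexes and SL pairs are added later by :func:`simulate_complexes`.
    """
    rng = config.rng(_STREAM_UNIVERSE)
    genes = np.array([f"G{i:06d}" for i in range(1, config.n_genes + 1)])

    cin = rng.choice(genes, size=config.n_cin, replace=False)
    cin_set = frozenset(cin.tolist())
    n_cancer = int(np.rint(config.n_cin * config.cancer_fraction))
    cancer = rng.choice(np.sort(cin), size=n_cancer, replace=False)
    cancer_set = frozenset(cancer.tolist())

    non_cin = np.sort(genes[~np.isin(genes, cin)])
    hubs = rng.choice(non_cin, size=config.n_hubs, replace=False)
    hub_set = frozenset(hubs.tolist())

    n_ess = int(np.rint(config.n_genes * config.essential_fraction))
    essential_flags = np.zeros(config.n_genes, dtype=bool)
    essential_flags[rng.choice(config.n_genes, size=n_ess, replace=False)] = True
    # hubs model essential-array mutants, so force them essential
    essential_flags[np.isin(genes, hubs)] = True

    groups = rng.choice(np.array(FUNCTIONAL_GROUPS), size=config.n_genes)

    cin_sorted = np.sort(cin)
    planted = set()
    for hub in sorted(hub_set):
        queries = rng.choice(cin_sorted, size=config.hub_cin_degree, replace=False)
        planted.update((q, hub) for q in queries.tolist())

    n_sens = int(np.rint(config.n_genes * config.sensitive_fraction))
    sensitive = {
        chem: frozenset(rng.choice(genes, size=n_sens, replace=False).tolist())
        for chem in config.chemicals
    }

    annotation = pd.DataFrame({
        "gene": genes,
        "essential": essential_flags,
        "is_cin": np.isin(genes, cin),
        "is_cancer_ortholog": np.isin(genes, cancer),
        "functional_group": groups,
    })
    truth = PlantedTruth(
        hub_genes=hub_set,
        planted_edges=frozenset(planted),
        sensitive_genes_by_chemical=sensitive,
        genes=tuple(genes.tolist()),
        cin_genes=cin_set,
        cancer_genes=cancer_set,
        essential_genes=frozenset(genes[essential_flags].tolist()),
        config_fingerprint=_fingerprint(config),
    )
    return annotation, truth


# ---------------------------------------------------------------------------
# Genetic-interaction screen


def simulate_gi_screen(config: SimulationConfig, truth: PlantedTruth) -> pd.DataFrame:
    """Simulate the CIN-query x array genetic-interaction screen.

    Every planted (CIN query, hub) edge is measured; in addition each
    non-planted (query, array) pair is measured with probability
    ``background_edge_prob``. A pair's reported score is the mean of three
    simulated replicate scores drawn N(mu, score_noise_sd * sqrt(3)) — so the
    score itself is distributed N(mu, score_noise_sd), mu being
    ``interaction_score_mean`` for planted edges and 0 otherwise — and its
    p-value comes from a two-sided one-sample t-test of those replicates
    against zero. With zero noise the t-test degenerates: p=0 for a nonzero
    mean, p=1 otherwise.
    """
    _check_truth(config, truth)
    rng = config.rng(_STREAM_GI)
    queries = np.array(sorted(truth.cin_genes))
    arrays = np.array(truth.genes)

    # candidate background pairs: all query x array minus self and planted
    mask = rng.random((len(queries), len(arrays))) < config.background_edge_prob
    qi, ai = np.nonzero(mask)
    bg_q, bg_a = queries[qi], arrays[ai]
    keep = bg_q != bg_a
    planted_pairs = truth.planted_edges
    if planted_pairs:
        keep &= ~np.fromiter(
            ((q, a) in planted_pairs for q, a in zip(bg_q, bg_a)),
            dtype=bool, count=len(bg_q))
    bg_q, bg_a = bg_q[keep], bg_a[keep]

    pl = sorted(planted_pairs)
    all_q = np.concatenate([bg_q, np.array([q for q, _ in pl], dtype=bg_q.dtype)]) \
        if pl else bg_q
    all_a = np.concatenate([bg_a, np.array([a for _, a in pl], dtype=bg_a.dtype)]) \
        if pl else bg_a
    mu = np.concatenate([np.zeros(len(bg_q)),
                         np.full(len(pl), config.interaction_score_mean)])

    n = len(all_q)
    reps = rng.normal(mu[:, None], config.score_noise_sd * np.sqrt(3.0), size=(n, 3))
    # zero-noise limit: report the planted mean exactly, not a rounded mean
    score = mu.copy() if config.score_noise_sd == 0 else reps.mean(axis=1)
    if config.score_noise_sd == 0:
        p = np.where(score != 0, 0.0, 1.0)
    else:
        se = reps.std(axis=1, ddof=1) / np.sqrt(3.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(score) / se
        p = 2.0 * stats.t.sf(t, df=2)
        degenerate = se == 0
        p[degenerate] = np.where(score[degenerate] != 0, 0.0, 1.0)

    out = pd.DataFrame({"query": all_q, "array": all_a,
                        "score": score, "p_value": p})
    return out.sort_values(["query", "array"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Chemical-sensitivity screen


def simulate_chemical_screen(config: SimulationConfig, truth: PlantedTruth) -> pd.DataFrame:
    """Replicated colony sizes per strain x chemical, with matched controls.

    Sensitive strains grow to ``colony_size_mean * sensitive_growth_ratio``
    on chemical; all strains grow to ``colony_size_mean`` on the matched
    no-chemical control plates. Noise is multiplicative log-normal with
    coefficient of variation ``colony_noise_cv``.
    """
    _check_truth(config, truth)
    rng = config.rng(_STREAM_CHEM)
    strains = np.array(truth.genes)
    n_rep = config.n_chem_replicates
    frames = []
    for chem in config.chemicals:
        sens = truth.sensitive_genes_by_chemical.get(chem, frozenset())
        is_sens = np.isin(strains, sorted(sens))
        chem_mean = config.colony_size_mean * np.where(
            is_sens, config.sensitive_growth_ratio, 1.0)
        for is_control, means in ((False, chem_mean),
                                  (True, np.full(len(strains), config.colony_size_mean))):
            sizes = _lognormal_noise(rng, means[:, None], config.colony_noise_cv,
                                     (len(strains), n_rep))
            frames.append(pd.DataFrame({
                "strain": np.repeat(strains, n_rep),
                "chemical": chem,
                "replicate": np.tile(np.arange(1, n_rep + 1), len(strains)),
                "colony_size": sizes.ravel(),
                "is_control": is_control,
            }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chemical", "strain", "is_control", "replicate"],
                           kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Protein complexes and SL-pair propagation


def simulate_complexes(config: SimulationConfig, truth: PlantedTruth) -> pd.DataFrame:
    """Assign essential partner genes to hub-anchored protein complexes.

    Each of ``n_complexes`` distinct hubs receives ``complex_size`` distinct
    essential partners (no partner reuse across complexes). Partners inherit
    their hub's SL structure: for every cancer-ortholog CIN query planted
    adjacent to the hub, the (partner, query) pair becomes a planted SL pair
    with defect ``planted_defect``. Fills ``truth.complexes`` and
    ``truth.sl_pairs`` in place and returns the membership table.
    """
    _check_truth(config, truth)
    if config.n_complexes > len(truth.hub_genes):
        raise ConfigurationError(
            f"n_complexes={config.n_complexes} exceeds the number of hubs "
            f"({len(truth.hub_genes)})")
    rng = config.rng(_STREAM_COMPLEX)
    pool = np.array(sorted(truth.essential_genes - truth.hub_genes))
    needed = config.n_complexes * config.complex_size
    if needed > len(pool):
        raise ConfigurationError(
            f"complexes need {needed} essential partner genes but only "
            f"{len(pool)} are available")

    hubs = rng.choice(np.array(sorted(truth.hub_genes)),
                      size=config.n_complexes, replace=False)
    partners = rng.choice(pool, size=needed, replace=False)

    truth.complexes = {}
    truth.sl_pairs = {}
    rows = []
    for i, hub in enumerate(hubs.tolist()):
        members = partners[i * config.complex_size:(i + 1) * config.complex_size]
        members = sorted(members.tolist())
        label = f"CPX{i + 1:03d}"
        truth.complexes[hub] = frozenset(members)
        profile = {q for q, a in truth.planted_edges
                   if a == hub and q in truth.cancer_genes}
        for partner in members:
            rows.append({"hub": hub, "partner": partner, "complex_label": label})
            for cancer_gene in profile:
                truth.sl_pairs[_canon_pair(partner, cancer_gene)] = config.planted_defect
    out = pd.DataFrame(rows, columns=["hub", "partner", "complex_label"])
    return out.sort_values(["complex_label", "partner"],
                           kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Proliferation (single/double knockdown)


def simulate_proliferation(config: SimulationConfig, truth: PlantedTruth) -> pd.DataFrame:
    """Simulate nuclei counts under a multiplicative interaction model.

    Control wells have mean count C; each single knockdown of gene *i* has
    mean C*s_i with s_i drawn uniformly from ``single_kd_effect_range``; the
    double knockdown of (i, j) has mean C*s_i*s_j*(1 - delta_ij), where
    delta_ij is the planted defect for SL pairs and 0 otherwise. In addition
    to the planted SL pairs, ``n_null_pairs`` random non-SL pairs are
    measured so the multiplicative null is represented. Counts carry
    multiplicative log-normal noise with CV ``proliferation_noise_cv`` and
    are replicated ``n_prolif_replicates`` times per condition.
    """
    _check_truth(config, truth)
    rng = config.rng(_STREAM_PROLIF)
    pairs = sorted(truth.sl_pairs)
    genes = np.array(truth.genes)
    sl_pair_set = set(pairs)
    null_pairs: list[tuple[str, str]] = []
    while len(null_pairs) < config.n_null_pairs:
        a, b = rng.choice(genes, size=2, replace=False)
        pair = _canon_pair(str(a), str(b))
        if pair not in sl_pair_set and pair not in null_pairs:
            null_pairs.append(pair)
    all_pairs = pairs + sorted(null_pairs)

    involved = sorted({g for pair in all_pairs for g in pair})
    lo, hi = config.single_kd_effect_range
    effects = dict(zip(involved, rng.uniform(lo, hi, size=len(involved))))

    cond_means: list[tuple[str, float]] = [("control", config.prolif_count_mean)]
    for g in involved:
        cond_means.append((f"single:{g}", config.prolif_count_mean * effects[g]))
    for a, b in all_pairs:
        delta = truth.sl_pairs.get((a, b), 0.0)
        mean = config.prolif_count_mean * effects[a] * effects[b] * (1.0 - delta)
        cond_means.append((f"double:{a}+{b}", mean))

    n_rep = config.n_prolif_replicates
    means = np.array([m for _, m in cond_means])
    counts = _lognormal_noise(rng, means[:, None], config.proliferation_noise_cv,
                              (len(cond_means), n_rep))
    out = pd.DataFrame({
        "condition": np.repeat([c for c, _ in cond_means], n_rep),
        "replicate": np.tile(np.arange(1, n_rep + 1), len(cond_means)),
        "count": counts.ravel(),
    })
    return out.sort_values(["condition", "replicate"],
                           kind="mergesort").reset_index(drop=True)
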