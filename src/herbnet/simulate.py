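"""Synthetic TCMSP-like inputs with known ground truth.

Every downstream stage (screen, target mapping, network topology,
enrichment) is testable offline against data whose true structure is known:

* per-herb ingredient catalogues whose OB/DL/HL marginals follow realistic
  right-skewed distributions (lognormal OB with median 25 %, Beta drug-
  likeness with mode 0.2, gamma half-life with median 6 h) — under the
  default three-axis screen roughly one ingredient in ten survives, and the
  exact pass rate is available in closed form from the configured
  distributions;
* compound-target likelihood matrices with planted hub compounds (true pairs
  score ~ Normal(9, 1), background pairs ~ Normal(3, 1.5), so a threshold of
  7 separates them sharply);
* annotation universes with planted enriched terms at a configurable odds
  ratio.

One global seed is expanded into independent substreams for the three
generators, so any stage can be regenerated without rerunning the others;
output is byte-identical under a fixed seed.  No chemistry is simulated:
descriptor values are drawn, never computed from structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .adme import ScreeningCriteria
from .errors import ConfigError
from .io_tables import IngredientRecord
from .targets import CompoundTargetPair

__all__ = [
    "Dist",
    "SimulationConfig",
    "SimulatedLikelihoods",
    "AnnotationGroundTruth",
    "gen_catalogue",
    "gen_likelihood_matrix",
    "gen_annotations",
    "expected_pass_rate",
    "write_simulated_inputs",
]


@dataclass(frozen=True)
class Dist:
    """A small named parametric distribution (draws + closed-form tails).

    Supported names: ``lognormal`` (median, sigma), ``beta`` (a, b),
    ``gamma`` (shape, scale), ``normal`` (mean, sd) and ``point`` (value,
    a degenerate point mass for exact-control tests).
    """

    name: str
    params: Mapping[str, float]

    def _frozen(self):
        p = self.params
        if self.name == "lognormal":
            return stats.lognorm(s=p["sigma"], scale=p["median"])
        if self.name == "beta":
            return stats.beta(p["a"], p["b"])
        if self.name == "gamma":
            return stats.gamma(p["shape"], scale=p["scale"])
        if self.name == "normal":
            return stats.norm(loc=p["mean"], scale=p["sd"])
        raise ConfigError(f"unknown distribution {self.name!r}")

    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.name == "point":
            return np.full(size, float(self.params["value"]))
        return self._frozen().rvs(size=size, random_state=rng)

    def prob_ge(self, x: float) -> float:
        """P(X >= x) (point masses included)."""
        if self.name == "point":
            return 1.0 if self.params["value"] >= x else 0.0
        return float(self._frozen().sf(x))

    def prob_between(self, lo: float, hi: float) -> float:
        """P(lo <= X <= hi) for continuous laws; exact for point masses."""
        if self.name == "point":
            return 1.0 if lo <= self.params["value"] <= hi else 0.0
        fz = self._frozen()
        return float(fz.cdf(hi) - fz.cdf(lo))


def _default_ob() -> Dist:
    return Dist("lognormal", {"median": 25.0, "sigma": 0.8})


def _default_dl() -> Dist:
    return Dist("beta", {"a": 2.0, "b": 5.0})


def _default_hl() -> Dist:
    # Gamma(shape=2) has median 1.6783 * scale; scale chosen for median 6 h.
    return Dist("gamma", {"shape": 2.0, "scale": 3.575})


def _default_true() -> Dist:
    return Dist("normal", {"mean": 9.0, "sd": 1.0})


def _default_background() -> Dist:
    return Dist("normal", {"mean": 3.0, "sd": 1.5})


#: Per-herb ingredient counts of a realistic four-herb formula catalogue.
DEFAULT_HERBS: tuple[tuple[str, int], ...] = (
    ("Panax ginseng", 190),
    ("Astragalus membranaceus", 87),
    ("Pulsatilla chinensis", 57),
    ("Coptis chinensis", 48),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic-data generators.

    A fixed ``seed`` makes every generator byte-identical across runs; the
    seed is expanded into one substream per generator (catalogue, likelihood,
    annotation) so stages are independently reproducible.
    """

    seed: int = 0
    herbs: tuple[tuple[str, int], ...] = DEFAULT_HERBS
    ob_dist: Dist = field(default_factory=_default_ob)
    dl_dist: Dist = field(default_factory=_default_dl)
    hl_dist: Dist = field(default_factory=_default_hl)
    n_compounds: int = 41
    n_targets: int = 94
    hub_compounds: tuple[tuple[int, int], ...] = ((0, 73), (1, 35), (2, 26))
    hub_targets: tuple[tuple[int, int], ...] = ()
    baseline_targets_per_compound: int = 5
    true_dist: Dist = field(default_factory=_default_true)
    background_dist: Dist = field(default_factory=_default_background)
    n_terms: int = 40
    planted_terms: tuple[tuple[int, float], ...] = ()
    term_base_prob: float = 0.1
    query_size: int = 40

    def __post_init__(self) -> None:
        for name, n in self.herbs:
            if n < 0:
                raise ConfigError(f"herb {name!r}: negative ingredient count {n}")
        for label, n in (("n_compounds", self.n_compounds),
                         ("n_targets", self.n_targets),
                         ("n_terms", self.n_terms),
                         ("baseline_targets_per_compound",
                          self.baseline_targets_per_compound),
                         ("query_size", self.query_size)):
            if n < 0:
                raise ConfigError(f"{label} must be >= 0, got {n}")
        for idx_list, bound, label in (
                (self.hub_compounds, self.n_compounds, "hub compound"),
                (self.hub_targets, self.n_targets, "hub target")):
            seen: set[int] = set()
            for idx, count in idx_list:
                if not (0 <= idx < bound):
                    raise ConfigError(f"{label} index {idx} out of range")
                if idx in seen:
                    raise ConfigError(
                        f"overlapping {label} specification at index {idx}")
                seen.add(idx)
                if count < 0 or (label == "hub compound" and count > self.n_targets) \
                        or (label == "hub target" and count > self.n_compounds):
                    raise ConfigError(f"{label} count {count} infeasible")
        if self.baseline_targets_per_compound > self.n_targets:
            raise ConfigError("baseline_targets_per_compound exceeds n_targets")
        if len(self.planted_terms) > self.n_terms:
            raise ConfigError("more planted terms than terms")
        seen_t: set[int] = set()
        for idx, odds in self.planted_terms:
            if not (0 <= idx < self.n_terms):
                raise ConfigError(f"planted term index {idx} out of range")
            if idx in seen_t:
                raise ConfigError(f"planted term index {idx} repeated")
            seen_t.add(idx)
            if odds <= 0:
                raise ConfigError(f"enrichment odds must be > 0, got {odds}")
        if not (0.0 < self.term_base_prob < 1.0):
            raise ConfigError("term_base_prob must lie in (0, 1)")
        if self.query_size > self.n_targets:
            raise ConfigError("query_size exceeds n_targets")

    def substreams(self) -> tuple[np.random.Generator, ...]:
        children = np.random.SeedSequence(self.seed).spawn(3)
        return tuple(np.random.default_rng(c) for c in children)

    def compound_ids(self) -> list[str]:
        return [f"C{i:03d}" for i in range(self.n_compounds)]

    def target_ids(self) -> list[str]:
        return [f"T{j:03d}" for j in range(self.n_targets)]


def gen_catalogue(config: SimulationConfig) -> list[IngredientRecord]:
    """Draw a per-herb ingredient catalogue with configured OB/DL/HL marginals."""
    rng, _, _ = config.substreams()
    records: list[IngredientRecord] = []
    for herb, n in config.herbs:
        ob = config.ob_dist.rvs(rng, n)
        dl = np.clip(config.dl_dist.rvs(rng, n), 0.0, 1.0)
        hl = np.abs(config.hl_dist.rvs(rng, n))
        slug = herb.split()[0].lower()
        for i in range(n):
            records.append(IngredientRecord(
                ingredient_id=f"{slug}-{i:04d}",
                name=f"{herb} ingredient {i}",
                herb=herb,
                ob=float(ob[i]), dl=float(dl[i]), hl=float(hl[i])))
    return records


def expected_pass_rate(config: SimulationConfig,
                       criteria: ScreeningCriteria | None = None) -> float:
    """Closed-form probability that one simulated ingredient passes the screen.

    OB, DL and HL are drawn independently, so the pass rate is the product of
    the three marginal tail probabilities implied by the configured
    distributions and thresholds.
    """
    c = criteria if criteria is not None else ScreeningCriteria()
    return (config.ob_dist.prob_ge(c.ob_min)
            * config.dl_dist.prob_ge(c.dl_min)
            * config.hl_dist.prob_between(c.hl_min, c.hl_max))


@dataclass(frozen=True)
class SimulatedLikelihoods:
    """A full compound x target likelihood table plus its planted truth."""

    pairs: tuple[CompoundTargetPair, ...]
    true_pairs: frozenset[tuple[str, str]]
    compounds: tuple[str, ...]
    targets: tuple[str, ...]


def gen_likelihood_matrix(config: SimulationConfig) -> SimulatedLikelihoods:
    """Score every compound-target pair, planting hub structure.

    Each planted hub compound receives its configured number of true targets
    (drawn uniformly without replacement); each planted hub target receives
    its configured number of true compounds, drawn from non-hub compounds so
    that hub-compound degrees stay exactly as configured.  Remaining
    compounds each receive ``baseline_targets_per_compound`` true targets.
    True pairs score from ``true_dist``, all others from ``background_dist``.
    """
    _, rng, _ = config.substreams()
    compounds = config.compound_ids()
    targets = config.target_ids()
    hub_c = dict(config.hub_compounds)
    hub_t = dict(config.hub_targets)
    true_cells: set[tuple[int, int]] = set()
    for i in range(config.n_compounds):
        n_true = hub_c.get(i, config.baseline_targets_per_compound)
        cols = rng.choice(config.n_targets, size=n_true, replace=False)
        true_cells.update((i, int(j)) for j in cols)
    non_hub = [i for i in range(config.n_compounds) if i not in hub_c]
    for j, count in hub_t.items():
        pool = non_hub if len(non_hub) >= count else list(range(config.n_compounds))
        rows = rng.choice(len(pool), size=count, replace=False)
        true_cells.update((pool[int(r)], j) for r in rows)
    n_cells = config.n_compounds * config.n_targets
    true_scores = config.true_dist.rvs(rng, n_cells)
    bg_scores = config.background_dist.rvs(rng, n_cells)
    pairs: list[CompoundTargetPair] = []
    for i, cid in enumerate(compounds):
        for j, tid in enumerate(targets):
            flat = i * config.n_targets + j
            score = true_scores[flat] if (i, j) in true_cells else bg_scores[flat]
            pairs.append(CompoundTargetPair(cid, tid, float(score)))
    truth = frozenset((compounds[i], targets[j]) for i, j in true_cells)
    return SimulatedLikelihoods(pairs=tuple(pairs), true_pairs=truth,
                                compounds=tuple(compounds),
                                targets=tuple(targets))


@dataclass(frozen=True)
class AnnotationGroundTruth:
    """Which terms were planted (and at what odds) against which query set."""

    planted: Mapping[str, float]
    query: tuple[str, ...]


def gen_annotations(config: SimulationConfig
                    ) -> tuple[pd.DataFrame, AnnotationGroundTruth]:
    """Generate a (subject, term, kind) annotation table with planted terms.

    Background terms include each subject independently with probability
    ``term_base_prob``.  A planted term with odds ratio ``rho`` raises the
    inclusion probability of subjects in the designated query set (the first
    ``query_size`` subjects) to ``rho*p/(1-p+rho*p)`` — odds multiplied by
    ``rho`` — so ``rho = 1`` is exactly the null.
    """
    _, _, rng = config.substreams()
    subjects = config.target_ids()
    query = tuple(subjects[:config.query_size])
    qset = set(query)
    planted = {f"term{idx:03d}": odds for idx, odds in config.planted_terms}
    p0 = config.term_base_prob
    rows: list[tuple[str, str, str]] = []
    for t in range(config.n_terms):
        term_id = f"term{t:03d}"
        odds = planted.get(term_id, 1.0)
        p1 = odds * p0 / (1.0 - p0 + odds * p0)
        for s in subjects:
            p = p1 if s in qset else p0
            if rng.random() < p:
                rows.append((s, term_id, "pathway"))
    df = pd.DataFrame(rows, columns=["subject_id", "term_id", "term_kind"])
    return df, AnnotationGroundTruth(planted=planted, query=query)


def write_simulated_inputs(config: SimulationConfig,
                           out_dir: str | Path) -> dict[str, Path]:
    """Emit catalogue, likelihood-score and annotation TSVs for the pipeline.

    Files are written with fixed float formatting so a fixed seed yields
    byte-identical output.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"catalogue": out / "catalogue.tsv",
             "scores": out / "scores.tsv",
             "annotations": out / "annotations.tsv"}
    cat = gen_catalogue(config)
    pd.DataFrame([{"ingredient_id": r.ingredient_id, "name": r.name,
                   "herb": r.herb, "ob": r.ob, "dl": r.dl, "hl": r.hl}
                  for r in cat]).to_csv(
        paths["catalogue"], sep="\t", index=False, float_format="%.6f")
    sim = gen_likelihood_matrix(config)
    pd.DataFrame([{"compound_id": p.compound_id,
                   "target_uniprot": p.target_uniprot,
                   "likelihood": p.likelihood} for p in sim.pairs]).to_csv(
        paths["scores"], sep="\t", index=False, float_format="%.6f")
    ann, _ = gen_annotations(config)
    ann.to_csv(paths["annotations"], sep="\t", index=False)
    return paths
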