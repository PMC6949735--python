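"""One-command orchestration: screen -> map targets -> network -> enrich.

A single JSON-able config drives every stage; each run writes its resolved
config, all stage outputs and a manifest whose counts are recomputable from
the emitted files.  With fixed seeds a rerun is byte-identical (the manifest
carries no timestamps for exactly this reason; wall-clock context belongs to
logging).  Any stage failure aborts the run, removes partial outputs and
names the failing stage.

The ``paper_fixtures`` mode replays the packaged reference tables: the
41-ingredient catalogue with its curated bioactive set, and the synthetic
367-edge compound-target list realizing the printed degree sequences.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .adme import ScreeningCriteria, load_default_criteria, screen
from .enrich import TermUniverse, hypergeom_enrich
from .errors import HerbnetError
from .io_tables import (fixture_path, load_ct_edges, load_curated_ids,
                        load_table1, load_table2, read_annotation_table,
                        read_ingredient_catalogue, write_edge_list)
from .network import build_network, degree_report
from .simulate import SimulationConfig, write_simulated_inputs
from .targets import CompoundTargetPair, dedupe_targets, threshold_pairs

__all__ = ["RunManifest", "run_pipeline", "verify_fixtures", "FixtureCheck"]


@dataclass
class RunManifest:
    """Provenance and per-stage counts of one pipeline run."""

    version: str
    seed: int | None
    config_hash: str
    input_digests: dict[str, str]
    counts: dict[str, int]
    hub_rule: str
    outputs: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_config(config: Mapping[str, Any] | str | Path) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        return json.loads(Path(config).read_text(encoding="utf-8"))
    return dict(config)


def _read_scores(path: Path) -> list[CompoundTargetPair]:
    df = pd.read_csv(path, sep="\t")
    for col in ("compound_id", "target_uniprot", "likelihood"):
        if col not in df.columns:
            raise HerbnetError(f"{path}: scores table lacks column {col!r}")
    return [CompoundTargetPair(str(r.compound_id), str(r.target_uniprot),
                               float(r.likelihood))
            for r in df.itertuples(index=False)]


def run_pipeline(config: Mapping[str, Any] | str | Path,
                 out_dir: str | Path) -> RunManifest:
    """Run the full analysis described by ``config`` into ``out_dir``.

    Config keys (all optional unless noted): ``seed``; ``simulate`` (a
    :class:`~herbnet.simulate.SimulationConfig` field mapping — generates the
    inputs in-place); ``catalogue``/``scores``/``annotations`` (input paths);
    ``criteria`` (threshold mapping); ``cutoff`` (likelihood cutoff, default
    7); ``alpha``; ``hub_threshold``/``hub_strict``; ``include_curated``
    (path of ingredient ids to force-retain); ``paper_fixtures`` (bool).
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "configure"
    try:
        if cfg.get("paper_fixtures"):
            cfg.setdefault("catalogue", str(fixture_path("table1.tsv")))
            cfg.setdefault("include_curated", str(fixture_path("curated_bioactives.tsv")))
        seed = cfg.get("seed")
        if "simulate" in cfg:
            stage = "simulate"
            sim_cfg = SimulationConfig(**{"seed": seed or 0, **cfg["simulate"]})
            paths = write_simulated_inputs(sim_cfg, out / "inputs")
            cfg.setdefault("catalogue", str(paths["catalogue"]))
            cfg.setdefault("scores", str(paths["scores"]))
            cfg.setdefault("annotations", str(paths["annotations"]))
            written.extend(paths.values())

        # paths under out_dir are stored relative to it so that reruns into
        # different directories stay byte-identical
        portable = dict(cfg)
        for key in ("catalogue", "scores", "annotations", "include_curated"):
            if portable.get(key):
                p = Path(portable[key]).resolve()
                if p.is_relative_to(out.resolve()):
                    portable[key] = str(p.relative_to(out.resolve()))
        resolved = out / "resolved_config.json"
        resolved.write_text(json.dumps(portable, indent=2, sort_keys=True) + "\n",
                            encoding="utf-8")
        written.append(resolved)
        config_hash = _sha256(resolved)

        # --- screen ---------------------------------------------------
        stage = "screen"
        if "catalogue" not in cfg:
            raise HerbnetError("config lacks a 'catalogue' input")
        cat_path = Path(cfg["catalogue"])
        if not cat_path.exists():
            raise HerbnetError(f"catalogue file not found: {cat_path}")
        ingredients = read_ingredient_catalogue(cat_path)
        criteria = (ScreeningCriteria(**cfg["criteria"]) if "criteria" in cfg
                    else load_default_criteria())
        report = screen(ingredients, criteria)
        audit = out / "screen_audit.tsv"
        pd.DataFrame([{
            "ingredient_id": r.record.ingredient_id, "name": r.record.name,
            "herb": r.record.herb, "ob": r.record.ob, "dl": r.record.dl,
            "hl": r.record.hl, "passed": r.passed,
            "failed_criteria": ";".join(r.failed),
            "reasons": ";".join(f"{k}:{v}" for k, v in r.reasons.items()),
        } for r in report.rows]).to_csv(audit, sep="\t", index=False)
        written.append(audit)
        retained = {rec.ingredient_id for rec in report.passed}
        curated_flagged = 0
        if cfg.get("include_curated"):
            curated = pd.read_csv(cfg["include_curated"], sep="\t")[
                "ingredient_id"].astype(str).tolist()
            curated_flagged = sum(1 for c in curated if c not in retained)
            retained |= set(curated)

        # --- map targets ----------------------------------------------
        stage = "map-targets"
        if cfg.get("paper_fixtures") and "scores" not in cfg:
            ct = load_ct_edges()
            cutoff = float(cfg.get("cutoff", 7.0))
            pairs = [CompoundTargetPair(a, b, cutoff) for a, b in ct]
        else:
            if "scores" not in cfg:
                raise HerbnetError("config lacks a 'scores' input")
            scores_path = Path(cfg["scores"])
            if not scores_path.exists():
                raise HerbnetError(f"scores file not found: {scores_path}")
            pairs = _read_scores(scores_path)
            cutoff = float(cfg.get("cutoff", 7.0))
            pairs = [p for p in pairs if p.compound_id in retained]
            pairs = threshold_pairs(pairs, cutoff)
        interactions = dedupe_targets(pairs)
        edges_path = out / "ct_edges.tsv"
        write_edge_list(interactions.edges(), edges_path, dialect="tsv")
        written.append(edges_path)
        targets_path = out / "targets.tsv"
        pd.DataFrame({"uniprot_ac": list(interactions.targets),
                      "degree": [interactions.target_degree[t]
                                 for t in interactions.targets]}).to_csv(
            targets_path, sep="\t", index=False)
        written.append(targets_path)

        # --- network --------------------------------------------------
        stage = "analyze"
        net = build_network(interactions.edges(), "compound", "target")
        hub_threshold = int(cfg.get("hub_threshold", 10))
        hub_strict = bool(cfg.get("hub_strict", True))
        rep = degree_report(net, hub_threshold=hub_threshold, strict=hub_strict)
        rep_path = out / "degree_report.tsv"
        rep.to_frame().to_csv(rep_path, sep="\t", index=False)
        written.append(rep_path)

        # --- enrich ---------------------------------------------------
        n_significant = 0
        if cfg.get("annotations"):
            stage = "enrich"
            ann_path = Path(cfg["annotations"])
            if not ann_path.exists():
                raise HerbnetError(f"annotations file not found: {ann_path}")
            ann = read_annotation_table(ann_path)
            universe = TermUniverse.from_annotation_table(ann)
            analysis = hypergeom_enrich(interactions.targets, universe,
                                        alpha=float(cfg.get("alpha", 0.05)),
                                        fdr=bool(cfg.get("fdr", False)))
            enr_path = out / "enrichment.tsv"
            analysis.to_frame().to_csv(enr_path, sep="\t", index=False,
                                       float_format="%.6g")
            written.append(enr_path)
            n_significant = len(analysis.significant())

        stage = "manifest"
        counts = {
            "ingredients_in": len(ingredients),
            "compounds_passed_strict": report.n_pass,
            "compounds_retained": len(retained),
            "curated_noncompliant": curated_flagged,
            "pairs_accepted": interactions.n_pairs,
            "unique_targets": interactions.n_targets,
            "ct_edges": net.n_edges,
            "significant_terms": n_significant,
        }
        manifest = RunManifest(
            version=__version__, seed=seed, config_hash=config_hash,
            input_digests={name: _sha256(Path(cfg[name]))
                           for name in ("catalogue", "scores", "annotations")
                           if cfg.get(name) and Path(cfg[name]).exists()},
            counts=counts, hub_rule=rep.hub_rule,
            outputs=sorted(str(p.relative_to(out)) for p in written))
        (out / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
        return manifest
    except Exception as exc:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise HerbnetError(f"pipeline failed at stage {stage!r}: {exc}") from exc


@dataclass(frozen=True)
class FixtureCheck:
    name: str
    expected: Any
    actual: Any

    @property
    def ok(self) -> bool:
        return self.expected == self.actual


def verify_fixtures() -> list[FixtureCheck]:
    """Recompute every printed-number check on the packaged fixtures.

    Covers row counts, degree-column sums, the handshake identity of the
    synthetic edge-list realization against both printed degree sequences,
    the top-degree nodes, both hub rules and the strict-screen audit.
    """
    t1, t2 = load_table1(), load_table2()
    edges = load_ct_edges()
    net = build_network(edges, "compound", "target",
                        left_nodes=t1["ingredient_id"].tolist(),
                        right_nodes=t2["uniprot_ac"].tolist())
    rep_strict = degree_report(net, 10, strict=True)
    rep_incl = degree_report(net, 10, strict=False)
    ingredients = read_ingredient_catalogue(fixture_path("table1.tsv"))
    report = screen(ingredients)
    ld, rd = net.degree("left"), net.degree("right")
    checks = [
        FixtureCheck("table1 rows", 41, len(t1)),
        FixtureCheck("table2 rows", 94, len(t2)),
        FixtureCheck("table2 unique accessions", 94, t2["uniprot_ac"].nunique()),
        FixtureCheck("table1 degree sum", 367, int(t1["degree"].sum())),
        FixtureCheck("table2 degree sum", 367, int(t2["degree"].sum())),
        FixtureCheck("ct edges", 367, net.n_edges),
        FixtureCheck("ct compounds", 41, len(net.left)),
        FixtureCheck("ct targets", 94, len(net.right)),
        FixtureCheck("compound degrees match printed", True,
                     all(ld[r.ingredient_id] == r.degree
                         for r in t1.itertuples(index=False))),
        FixtureCheck("target degrees match printed", True,
                     all(rd[r.uniprot_ac] == r.degree
                         for r in t2.itertuples(index=False))),
        FixtureCheck("max compound degree", ("mol01", 73),
                     rep_strict.max_degree("left")),
        FixtureCheck("max target degree", ("P03372", 34),
                     rep_strict.max_degree("right")),
        FixtureCheck("target hubs (degree > 10)", 8,
                     len(rep_strict.right_hubs)),
        FixtureCheck("compound hubs (degree >= 10)", 8,
                     len(rep_incl.left_hubs)),
        FixtureCheck("strict screen passes", 18, report.n_pass),
        FixtureCheck("curated set size", 41, len(load_curated_ids())),
    ]
    return checks
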