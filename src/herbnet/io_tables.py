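"""Reading and writing of the tabular artifacts used throughout the pipeline.

The ingestion side accepts TSV or CSV exports in the style of the TCMSP
(Traditional Chinese Medicine Systems Pharmacology) database: one row per herb
ingredient carrying pharmacokinetic fields such as oral bioavailability (OB),
drug-likeness (DL) and half-life (HL).  Column names are matched
case-insensitively through a synonym map because real exports are not
consistent about headers ("OB (%)" vs "ob").

Two reference tables are shipped as package data, transcribed verbatim from
the printed source (including its typographic quirks, e.g. the "Homosapiens"
organism spelling): ``table1.tsv`` (41 formula ingredients with ADME fields
and compound-target degrees) and ``table2.tsv`` (94 unique protein targets
with degrees).  A synthetic compound-target edge list realizing both degree
sequences is shipped alongside (see :mod:`herbnet.targets`).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import TableFormatError, TableParseError

__all__ = [
    "IngredientRecord",
    "TargetRecord",
    "read_ingredient_catalogue",
    "read_target_table",
    "read_annotation_table",
    "write_edge_list",
    "read_edge_list",
    "fixture_path",
    "load_table1",
    "load_table2",
    "load_table1_records",
    "load_table2_records",
    "load_ct_edges",
    "load_curated_ids",
]

ANNOTATION_KINDS = ("disease", "pathway", "go_bp", "function_module")

# Case-insensitive header synonyms -> canonical field names.  Keys are
# lower-cased and stripped before lookup.
COLUMN_SYNONYMS: dict[str, str] = {
    "id": "ingredient_id",
    "mol id": "ingredient_id",
    "molecule id": "ingredient_id",
    "ingredient_id": "ingredient_id",
    "ingredient id": "ingredient_id",
    "name": "name",
    "compound": "name",
    "compounds": "name",
    "canonical_name": "canonical_name",
    "herb": "herb",
    "mw": "mw",
    "alogp": "alogp",
    "hdon": "hdon",
    "hodn": "hdon",  # printed misspelling in some exports
    "hacc": "hacc",
    "ob": "ob",
    "ob (%)": "ob",
    "ob(%)": "ob",
    "oral bioavailability": "ob",
    "caco-2": "caco2",
    "caco2": "caco2",
    "bbb": "bbb",
    "dl": "dl",
    "drug-likeness": "dl",
    "drug likeness": "dl",
    "fasa": "fasa",
    "fasa-": "fasa",
    "hl": "hl",
    "half-life": "hl",
    "half life": "hl",
    "degree": "degree",
    "rank": "rank",
    "uniprot": "uniprot_ac",
    "uniprot_ac": "uniprot_ac",
    "uniprot ac": "uniprot_ac",
    "accession": "uniprot_ac",
    "protein name": "protein_name",
    "protein names": "protein_name",
    "protein_name": "protein_name",
    "gene": "gene_symbol",
    "gene name": "gene_symbol",
    "gene names": "gene_symbol",
    "gene_symbol": "gene_symbol",
    "organism": "organism",
    "subject_id": "subject_id",
    "subject": "subject_id",
    "target": "term_id" ,  # annotation tables written as subject/target pairs
    "term_id": "term_id",
    "term": "term_id",
    "term_kind": "term_kind",
    "kind": "term_kind",
}


@dataclass(frozen=True)
class IngredientRecord:
    """One TCMSP-style ingredient row with its pharmacokinetic fields.

    ``ob`` is a percentage, ``hl`` is in hours, ``dl`` is the unitless
    drug-likeness index on [0, 1].  Optional descriptor fields that are absent
    in the source table are ``None`` — never 0, because 0 is a legal value.
    """

    ingredient_id: str
    name: str
    herb: str
    ob: float | None
    dl: float | None
    hl: float | None
    mw: float | None = None
    alogp: float | None = None
    hdon: int | None = None
    hacc: int | None = None
    caco2: float | None = None
    bbb: float | None = None
    fasa: float | None = None

    def __post_init__(self) -> None:
        if not self.ingredient_id:
            raise TableFormatError("ingredient_id must be non-empty")
        if self.ob is not None and self.ob < 0:
            raise TableFormatError(
                f"{self.ingredient_id}: OB must be >= 0, got {self.ob}")
        if self.dl is not None and not (0.0 <= self.dl <= 1.0):
            raise TableFormatError(
                f"{self.ingredient_id}: DL must lie in [0, 1], got {self.dl}")
        if self.hl is not None and self.hl < 0:
            raise TableFormatError(
                f"{self.ingredient_id}: HL must be >= 0, got {self.hl}")


@dataclass(frozen=True)
class TargetRecord:
    """One protein target: UniProt accession, names and organism."""

    uniprot_ac: str
    protein_name: str
    gene_symbol: str
    organism: str = ""

    def __post_init__(self) -> None:
        if not self.uniprot_ac:
            raise TableFormatError("uniprot_ac must be non-empty")
        object.__setattr__(self, "gene_symbol", self.gene_symbol.upper())


def _delimiter_for(path: Path) -> str:
    if path.suffix.lower() == ".csv":
        return ","
    return "\t"


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), dtype=str,
                     keep_default_na=False, encoding="utf-8")
    renames = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in COLUMN_SYNONYMS:
            renames[col] = COLUMN_SYNONYMS[key]
    return df.rename(columns=renames)


def _require_columns(df: pd.DataFrame, required: Sequence[str],
                     path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}")


def _parse_float(cell: str, column: str, row: int) -> float | None:
    cell = cell.strip()
    if cell == "" or cell.upper() in {"NA", "NAN", "NONE"}:
        return None
    try:
        return float(cell)
    except ValueError:
        raise TableParseError(
            f"row {row}: cannot parse {column}={cell!r} as a number") from None


def _parse_int(cell: str, column: str, row: int) -> int | None:
    value = _parse_float(cell, column, row)
    return None if value is None else int(round(value))


def read_ingredient_catalogue(path: str | Path,
                              herb: str | None = None) -> list[IngredientRecord]:
    """Read a per-herb ingredient catalogue (TSV or CSV).

    Parameters
    ----------
    path:
        Table with at least ``ingredient_id``, ``name``, ``ob``, ``dl``,
        ``hl`` columns (synonyms accepted, case-insensitive).
    herb:
        Herb name recorded on every row when the file has no ``herb`` column.

    Row order is preserved and ``ingredient_id`` must be unique.
    """
    df = _read_table(path)
    _require_columns(df, ["ingredient_id", "name", "ob", "dl", "hl"], path)
    records: list[IngredientRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        iid = row["ingredient_id"].strip()
        if iid in seen:
            raise TableFormatError(
                f"{path}: duplicated ingredient_id {iid!r} at row {i}")
        seen.add(iid)
        records.append(IngredientRecord(
            ingredient_id=iid,
            name=row["name"].strip(),
            herb=(row.get("herb") or herb or "").strip(),
            ob=_parse_float(row["ob"], "ob", i),
            dl=_parse_float(row["dl"], "dl", i),
            hl=_parse_float(row["hl"], "hl", i),
            mw=_parse_float(row.get("mw", ""), "mw", i),
            alogp=_parse_float(row.get("alogp", ""), "alogp", i),
            hdon=_parse_int(row.get("hdon", ""), "hdon", i),
            hacc=_parse_int(row.get("hacc", ""), "hacc", i),
            caco2=_parse_float(row.get("caco2", ""), "caco2", i),
            bbb=_parse_float(row.get("bbb", ""), "bbb", i),
            fasa=_parse_float(row.get("fasa", ""), "fasa", i),
        ))
    return records


def read_target_table(path: str | Path) -> list[TargetRecord]:
    """Read a protein-target table; gene symbols are normalized to uppercase.

    Duplicate UniProt accessions are rejected (the accession, not the gene
    symbol, is the target's identity).
    """
    df = _read_table(path)
    _require_columns(df, ["uniprot_ac", "protein_name", "gene_symbol"], path)
    records: list[TargetRecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        row = row._asdict()
        ac = row["uniprot_ac"].strip()
        if ac in seen:
            raise TableFormatError(f"{path}: duplicate accession {ac!r}")
        seen.add(ac)
        records.append(TargetRecord(
            uniprot_ac=ac,
            protein_name=row["protein_name"].strip(),
            gene_symbol=row["gene_symbol"].strip(),
            organism=row.get("organism", "").strip(),
        ))
    return records


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read a (subject_id, term_id, term_kind) annotation table.

    Duplicate (subject_id, term_id) rows are dropped after loading; the kind
    column must only contain known annotation kinds.
    """
    df = _read_table(path)
    _require_columns(df, ["subject_id", "term_id", "term_kind"], path)
    df = df[["subject_id", "term_id", "term_kind"]].astype(str)
    bad = set(df["term_kind"]) - set(ANNOTATION_KINDS)
    if bad:
        raise TableFormatError(
            f"{path}: unknown term_kind value(s): {sorted(bad)}; "
            f"expected one of {ANNOTATION_KINDS}")
    return df.drop_duplicates(["subject_id", "term_id"]).reset_index(drop=True)


Edge = tuple  # (left, right) or (left, right, weight)


def write_edge_list(edges: Iterable[Edge], path: str | Path,
                    dialect: str = "tsv", interaction: str = "ct") -> None:
    """Write edges as a two/three-column TSV or a Cytoscape SIF file.

    SIF has no quoting convention, so identifiers containing the delimiter
    are rejected outright rather than silently mangled.
    """
    path = Path(path)
    edges = list(edges)
    if dialect == "tsv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            has_weight = any(len(e) > 2 for e in edges)
            writer.writerow(["source", "target"] + (["weight"] if has_weight else []))
            for e in edges:
                for ident in e[:2]:
                    if "\t" in str(ident):
                        raise TableFormatError(
                            f"identifier {ident!r} contains the TSV delimiter")
                writer.writerow(list(e[:2]) + ([e[2]] if has_weight and len(e) > 2 else
                                               [""] if has_weight else []))
    elif dialect == "sif":
        with path.open("w", encoding="utf-8") as fh:
            for e in edges:
                left, right = str(e[0]), str(e[1])
                for ident in (left, right):
                    if "\t" in ident or " " in ident:
                        raise TableFormatError(
                            f"identifier {ident!r} contains the SIF delimiter")
                fh.write(f"{left}\t{interaction}\t{right}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'sif'")


def read_edge_list(path: str | Path) -> list[tuple[str, ...]]:
    """Read back an edge list written by :func:`write_edge_list`.

    The dialect is inferred: a three-column header-less file whose middle
    column repeats is treated as SIF.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if not rows:
        return []
    header = rows[0]
    if header[0] == "source":  # TSV with header
        out = []
        for r in rows[1:]:
            if len(r) >= 3 and r[2] != "":
                out.append((r[0], r[1], float(r[2])))
            else:
                out.append((r[0], r[1]))
        return out
    # SIF: source interaction target
    return [(r[0], r[2]) for r in rows]


# ---------------------------------------------------------------------------
# Packaged reference fixtures


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(str(resources.files("herbnet.data").joinpath(name)))


def load_table1() -> pd.DataFrame:
    """The 41-ingredient reference table, with printed degrees, as a frame."""
    df = pd.read_csv(fixture_path("table1.tsv"), sep="\t", encoding="utf-8")
    return df


def load_table2() -> pd.DataFrame:
    """The 94-target reference table, with printed degrees, as a frame."""
    return pd.read_csv(fixture_path("table2.tsv"), sep="\t", encoding="utf-8")


def load_table1_records() -> list[IngredientRecord]:
    return read_ingredient_catalogue(fixture_path("table1.tsv"))


def load_table2_records() -> list[TargetRecord]:
    return read_target_table(fixture_path("table2.tsv"))


def load_ct_edges() -> list[tuple[str, str]]:
    """The shipped synthetic compound-target edge list (367 edges).

    The source publication prints only the two degree sequences, not the
    edges; this fixture is a deterministic realization of both sequences
    (see :func:`herbnet.targets.realize_bipartite_degrees`).
    """
    return [(e[0], e[1]) for e in read_edge_list(fixture_path("ct_edges_synthetic.tsv"))]


def load_curated_ids() -> list[str]:
    """Ingredient ids of the curated bioactive set from the reference table."""
    df = pd.read_csv(fixture_path("curated_bioactives.tsv"), sep="\t")
    return df["ingredient_id"].astype(str).tolist()
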