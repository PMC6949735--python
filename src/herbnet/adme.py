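"""ADME-based bioactivity screening.

Three pharmacokinetic axes are screened jointly, mirroring common practice in
herbal-formula network pharmacology:

* **OB** — oral bioavailability (%), consumed as a precomputed field.
* **DL** — drug-likeness: a continuous Tanimoto similarity between a
  compound's molecular-descriptor vector and the average descriptor vector of
  a reference drug library,

  .. math:: T(x, y) = \\frac{x \\cdot y}{\\|x\\|^2 + \\|y\\|^2 - x \\cdot y}.

  Unlike the binary-fingerprint Jaccard index, this continuous form is *not*
  scale invariant — ``T(2x, y) != T(x, y)`` in general — which is a documented
  behaviour of the score, not a defect.
* **HL** — half-life (hours), predicted by an eight-descriptor linear QSPR
  model whose published point estimates ship in ``data/hl_model.json`` and can
  be overridden.

The default screen keeps compounds with OB >= 30 %, DL >= 0.18 and
4 h <= HL <= 8 h (all bounds inclusive) and returns a per-row audit of every
violated criterion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import HerbnetError
from .io_tables import IngredientRecord, fixture_path

__all__ = [
    "HL_DESCRIPTOR_NAMES",
    "HLModel",
    "ScreeningCriteria",
    "ScreenRow",
    "ScreenReport",
    "tanimoto_dl",
    "predict_hl",
    "screen",
    "retention_rate",
    "load_hl_model",
    "load_default_criteria",
]

#: The eight QSPR descriptors of the half-life model, in canonical order.
#: Names are identifier-safe spellings of the conventional descriptor labels
#: (D/Dr09 -> DDr09, N-070 -> N070, C-032 -> C032, nRC=N -> nRCeqN).
HL_DESCRIPTOR_NAMES = (
    "nArCO", "H7m", "DDr09", "N070", "C032", "JGI6", "nRCeqN", "Mor02e",
)


@dataclass(frozen=True)
class HLModel:
    """Linear half-life predictor: intercept plus eight descriptor terms.

    ``metadata`` stores the published fit statistics (R², Q², F, SEE, training
    and test sizes) for provenance only; they play no role in prediction.
    """

    intercept: float
    coef: Mapping[str, float]
    metadata: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = tuple(self.coef)
        if set(names) != set(HL_DESCRIPTOR_NAMES):
            raise HerbnetError(
                "HLModel coefficients must cover exactly the descriptors "
                f"{HL_DESCRIPTOR_NAMES}, got {names}")


def load_hl_model(path: str | Path | None = None) -> HLModel:
    """Load the half-life model, defaulting to the packaged coefficients."""
    path = fixture_path("hl_model.json") if path is None else Path(path)
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return HLModel(intercept=float(payload["intercept"]),
                   coef={k: float(v) for k, v in payload["coef"].items()},
                   metadata=payload.get("metadata", {}))


@dataclass(frozen=True)
class ScreeningCriteria:
    """Inclusive thresholds of the three-axis bioactivity screen."""

    ob_min: float = 30.0
    dl_min: float = 0.18
    hl_min: float = 4.0
    hl_max: float = 8.0

    def __post_init__(self) -> None:
        if self.ob_min < 0:
            raise HerbnetError(f"ob_min must be >= 0, got {self.ob_min}")
        if not (0.0 <= self.dl_min <= 1.0):
            raise HerbnetError(f"dl_min must lie in [0, 1], got {self.dl_min}")
        if self.hl_min > self.hl_max:
            raise HerbnetError(
                f"hl_min ({self.hl_min}) must not exceed hl_max ({self.hl_max})")


def load_default_criteria(path: str | Path | None = None) -> ScreeningCriteria:
    path = fixture_path("criteria_default.json") if path is None else Path(path)
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return ScreeningCriteria(**{k: float(v) for k, v in payload.items()})


def tanimoto_dl(x: Sequence[float], y: Sequence[float]) -> float:
    """Continuous Tanimoto drug-likeness score between descriptor vectors.

    ``x`` is a compound's descriptor vector and ``y`` a reference-library
    centroid of the same dimension.  The score is symmetric and equals 1 when
    ``x == y != 0``; it is undefined (raises) when both vectors are zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise HerbnetError(
            f"descriptor dimension mismatch: {x.shape} vs {y.shape}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise HerbnetError("descriptor vectors must be finite")
    dot = float(x @ y)
    denom = float(x @ x) + float(y @ y) - dot
    if denom == 0.0:
        raise HerbnetError(
            "Tanimoto score undefined: both descriptor vectors are zero")
    return dot / denom


def predict_hl(descriptors: Mapping[str, float],
               model: HLModel | None = None) -> float:
    """Predicted half-life (hours) from the eight-descriptor linear model."""
    if model is None:
        model = load_hl_model()
    missing = [k for k in HL_DESCRIPTOR_NAMES if k not in descriptors]
    if missing:
        raise HerbnetError(f"missing descriptor(s): {', '.join(missing)}")
    values = np.array([float(descriptors[k]) for k in HL_DESCRIPTOR_NAMES])
    if not np.isfinite(values).all():
        raise HerbnetError("descriptors must be finite")
    coefs = np.array([model.coef[k] for k in HL_DESCRIPTOR_NAMES])
    return float(model.intercept + values @ coefs)


@dataclass(frozen=True)
class ScreenRow:
    """Audit entry for one screened ingredient."""

    record: IngredientRecord
    passed: bool
    failed: tuple[str, ...]          # subset of ("OB", "DL", "HL")
    reasons: Mapping[str, str]       # criterion -> "below"/"above"/"missing"


@dataclass(frozen=True)
class ScreenReport:
    """Outcome of a screen: per-row audit plus summary counts.

    The pass and fail sets partition the input; a row passes iff its
    failed-criteria list is empty.
    """

    rows: tuple[ScreenRow, ...]
    criteria: ScreeningCriteria

    @property
    def passed(self) -> list[IngredientRecord]:
        return [r.record for r in self.rows if r.passed]

    @property
    def failed(self) -> list[ScreenRow]:
        return [r for r in self.rows if not r.passed]

    @property
    def n_total(self) -> int:
        return len(self.rows)

    @property
    def n_pass(self) -> int:
        return sum(1 for r in self.rows if r.passed)

    @property
    def retention_pct(self) -> float:
        return retention_rate(self.n_pass, self.n_total)


def _check_axis(value: float | None, lo: float, hi: float | None
                ) -> str | None:
    """Return None when the value satisfies [lo, hi], else the reason."""
    if value is None:
        return "missing"
    if value < lo:
        return "below"
    if hi is not None and value > hi:
        return "above"
    return None


def screen(ingredients: Sequence[IngredientRecord],
           criteria: ScreeningCriteria | None = None) -> ScreenReport:
    """Apply the three-criterion ADME screen with a full per-row audit.

    Every record is tested against all three axes (inclusive bounds); all
    violated criteria are recorded, and a missing OB/DL/HL value fails its
    criterion with reason ``"missing"``.  Pass order follows input order.
    """
    if criteria is None:
        criteria = ScreeningCriteria()
    rows: list[ScreenRow] = []
    for rec in ingredients:
        reasons: dict[str, str] = {}
        for axis, value, lo, hi in (
                ("OB", rec.ob, criteria.ob_min, None),
                ("DL", rec.dl, criteria.dl_min, None),
                ("HL", rec.hl, criteria.hl_min, criteria.hl_max)):
            why = _check_axis(value, lo, hi)
            if why is not None:
                reasons[axis] = why
        failed = tuple(k for k in ("OB", "DL", "HL") if k in reasons)
        rows.append(ScreenRow(record=rec, passed=not failed,
                              failed=failed, reasons=reasons))
    return ScreenReport(rows=tuple(rows), criteria=criteria)


def retention_rate(n_pass: int, n_total: int) -> float:
    """Percentage of records retained, half-up rounded to two decimals."""
    if n_total <= 0:
        raise HerbnetError("retention_rate requires n_total > 0")
    if not (0 <= n_pass <= n_total):
        raise HerbnetError(f"n_pass must lie in [0, {n_total}], got {n_pass}")
    pct = Decimal(100 * n_pass) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
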