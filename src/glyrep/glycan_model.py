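"""Glycan composition parsing, structural classification, trait algebra,
and phenotype preprocessing.

Composition codes follow the H#N#F#E#L#G# grammar: hexoses (H),
N-acetylhexosamines (N), fucoses (F), ethyl-esterified alpha2,6-linked
sialic acids (E), lactonized alpha2,3-linked sialic acids (L) and
hexuronic acids (G), each letter followed by an integer count.

Structural classification (antennarity, bisection, core vs antennary
fucose) uses deterministic heuristics that can be overridden per
composition with an explicit annotation mapping, since exact panel
definitions vary between laboratories.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

_LETTERS = ("H", "N", "F", "E", "L", "G")
_TOKEN_RE = re.compile(r"([A-Za-z]+)(\d*)")


class GlycanClass(str, Enum):
    OLIGOMANNOSE = "oligomannose"
    HYBRID = "hybrid"
    COMPLEX = "complex"


class CompositionError(ValueError):
    """Malformed glycan composition code."""


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide counts of one glycan composition."""

    hexose: int = 0
    hexnac: int = 0
    fucose: int = 0
    neu5ac_a26: int = 0  # E: ethyl-esterified alpha2,6-linked sialic acid
    neu5ac_a23: int = 0  # L: lactonized alpha2,3-linked sialic acid
    hexuronic: int = 0  # G: hexuronic acid

    def __post_init__(self) -> None:
        counts = self.as_dict()
        for letter, c in counts.items():
            if c < 0:
                raise CompositionError(f"negative count for {letter}: {c}")
        if self.hexose == 0 and self.hexnac == 0:
            raise CompositionError("composition must contain at least one H or N")

    def as_dict(self) -> dict[str, int]:
        return {
            "H": self.hexose,
            "N": self.hexnac,
            "F": self.fucose,
            "E": self.neu5ac_a26,
            "L": self.neu5ac_a23,
            "G": self.hexuronic,
        }

    @property
    def code(self) -> str:
        """Canonical code string: letters in H,N,F,E,L,G order, zeros omitted."""
        return "".join(
            f"{letter}{count}" for letter, count in self.as_dict().items() if count > 0
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


_FIELD_BY_LETTER = {
    "H": "hexose",
    "N": "hexnac",
    "F": "fucose",
    "E": "neu5ac_a26",
    "L": "neu5ac_a23",
    "G": "hexuronic",
}


def parse_composition(code: str) -> GlycanComposition:
    """Parse a composition code such as ``"H5N4F1E1L1"``.

    Letters may appear in any order, at most once each; absent letters
    mean a count of zero. Raises :class:`CompositionError` naming the
    offending token on malformed input.
    """
    if not isinstance(code, str) or not code.strip():
        raise CompositionError("empty composition code")
    code = code.strip()
    seen: dict[str, int] = {}
    pos = 0
    for m in _TOKEN_RE.finditer(code):
        if m.start() != pos:
            raise CompositionError(
                f"unexpected token {code[pos:m.start()]!r} in {code!r}"
            )
        pos = m.end()
        letter, digits = m.group(1), m.group(2)
        if len(letter) != 1 or letter.upper() not in _LETTERS:
            raise CompositionError(f"unknown letter {letter!r} in {code!r}")
        letter = letter.upper()
        if letter in seen:
            raise CompositionError(f"repeated letter {letter!r} in {code!r}")
        if not digits:
            raise CompositionError(f"missing integer after {letter!r} in {code!r}")
        seen[letter] = int(digits)
    if pos != len(code):
        raise CompositionError(f"unexpected token {code[pos:]!r} in {code!r}")
    kwargs = {_FIELD_BY_LETTER[letter]: count for letter, count in seen.items()}
    return GlycanComposition(**kwargs)


@dataclass(frozen=True)
class GlycanFeatures:
    """Structural features derived from a composition."""

    glycan_class: GlycanClass
    antennae: int
    bisected: bool
    core_fucosylated: bool
    antennary_fucose: int
    sialyl_a26: int
    sialyl_a23: int
    galactoses_on_antennae: int

    def as_dict(self) -> dict[str, object]:
        d = {
            "glycan_class": self.glycan_class.value,
            "antennae": self.antennae,
            "bisected": self.bisected,
            "core_fucosylated": self.core_fucosylated,
            "antennary_fucose": self.antennary_fucose,
            "sialyl_a26": self.sialyl_a26,
            "sialyl_a23": self.sialyl_a23,
            "galactoses_on_antennae": self.galactoses_on_antennae,
        }
        return d


def classify_glycan(
    comp: GlycanComposition,
    overrides: Mapping[str, GlycanFeatures] | None = None,
) -> GlycanFeatures:
    """Classify a composition into structural features.

    Heuristic rule set (overridable per composition via ``overrides``,
    keyed by canonical code):

    * oligomannose iff N = 2, H >= 4 and no sialic acids;
    * hybrid iff N = 3 and H >= 5; otherwise complex;
    * bisecting GlcNAc flagged when N >= 5 and H <= N - 1 (the extra N
      cannot be an additional galactosylated antenna), in which case
      antennae = N - 3; otherwise antennae = N - 2, capped at 4;
    * core fucosylation iff F >= 1; fucoses beyond the first count as
      antennary on tri-/tetra-antennary structures;
    * galactoses on antennae = max(H - 3, 0), capped at the antenna count.
    """
    if overrides is not None:
        hit = overrides.get(comp.code)
        if hit is not None:
            return hit

    H, N = comp.hexose, comp.hexnac
    sia26, sia23 = comp.neu5ac_a26, comp.neu5ac_a23

    if N == 2 and H >= 4 and sia26 == 0 and sia23 == 0:
        return GlycanFeatures(
            glycan_class=GlycanClass.OLIGOMANNOSE,
            antennae=0,
            bisected=False,
            core_fucosylated=comp.fucose >= 1,
            antennary_fucose=0,
            sialyl_a26=0,
            sialyl_a23=0,
            galactoses_on_antennae=0,
        )

    bisected = N >= 5 and H <= N - 1
    antennae = N - 3 if bisected else N - 2
    antennae = max(0, min(antennae, 4))
    glycan_class = GlycanClass.HYBRID if (N == 3 and H >= 5) else GlycanClass.COMPLEX
    core_fuc = comp.fucose >= 1
    ant_fuc = max(comp.fucose - 1, 0) if antennae >= 3 else 0
    gal = min(max(H - 3, 0), antennae)
    return GlycanFeatures(
        glycan_class=glycan_class,
        antennae=antennae,
        bisected=bisected,
        core_fucosylated=core_fuc,
        antennary_fucose=ant_fuc,
        sialyl_a26=sia26,
        sialyl_a23=sia23,
        galactoses_on_antennae=gal,
    )


# ---------------------------------------------------------------------------
# Trait definitions and evaluation
# ---------------------------------------------------------------------------

class TraitConfigError(ValueError):
    """Invalid trait definition (bad selector, missing peak, ...)."""


_SELECTOR_FIELDS = {
    "H": lambda c, f: c.hexose,
    "N": lambda c, f: c.hexnac,
    "F": lambda c, f: c.fucose,
    "E": lambda c, f: c.neu5ac_a26,
    "L": lambda c, f: c.neu5ac_a23,
    "G": lambda c, f: c.hexuronic,
    "S": lambda c, f: c.neu5ac_a26 + c.neu5ac_a23,  # total sialic acids
    "antennae": lambda c, f: f.antennae,
    "bisected": lambda c, f: int(f.bisected),
    "core_fucosylated": lambda c, f: int(f.core_fucosylated),
    "antennary_fucose": lambda c, f: f.antennary_fucose,
    "galactoses": lambda c, f: f.galactoses_on_antennae,
    "class": lambda c, f: f.glycan_class.value,
}

_CLAUSE_RE = re.compile(
    r"^\s*(?P<field>[A-Za-z_]+)\s*(?P<op>==|=|!=|>=|<=|>|<)\s*(?P<value>\w+)\s*$"
)
_OPS: dict[str, Callable[[object, object], bool]] = {
    "=": lambda a, b: a == b,
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
    ">=": lambda a, b: a >= b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    "<": lambda a, b: a < b,
}


def _match_selector(selector: str, comp: GlycanComposition, feats: GlycanFeatures) -> bool:
    """Evaluate a feature-selector expression like ``"antennae=2 & F>=1"``.

    A selector is either a bare composition code (exact match on the
    canonical code) or ``&``-joined comparison clauses over composition
    letters (H,N,F,E,L,G, S for E+L) and feature names (antennae,
    bisected, core_fucosylated, antennary_fucose, galactoses, class).
    ``"*"`` matches every glycan.
    """
    selector = selector.strip()
    if selector == "*":
        return True
    if "&" not in selector and _CLAUSE_RE.match(selector) is None:
        # bare composition code
        try:
            return parse_composition(selector).code == comp.code
        except CompositionError as exc:
            raise TraitConfigError(f"bad selector {selector!r}: {exc}") from exc
    for clause in selector.split("&"):
        m = _CLAUSE_RE.match(clause)
        if m is None:
            raise TraitConfigError(f"bad selector clause {clause!r}")
        name, op, raw = m.group("field"), m.group("op"), m.group("value")
        if name not in _SELECTOR_FIELDS:
            raise TraitConfigError(f"unknown selector field {name!r}")
        lhs = _SELECTOR_FIELDS[name](comp, feats)
        rhs: object
        if name == "class":
            rhs = raw
        else:
            try:
                rhs = int(raw)
            except ValueError as exc:
                raise TraitConfigError(f"non-integer value in clause {clause!r}") from exc
        if not _OPS[op](lhs, rhs):
            return False
    return True


_WEIGHT_TOKEN_RE = re.compile(r"^[\w\s\.\+\-\*\/\(\)]*$")


def _eval_weight(expr: str | float | int, comp: GlycanComposition, feats: GlycanFeatures) -> float:
    """Evaluate a per-glycan weight: a number or an arithmetic expression
    over composition letters and feature counts (e.g. ``"E"``, ``"E+L"``)."""
    if isinstance(expr, (int, float)):
        return float(expr)
    expr = expr.strip()
    if not expr:
        return 1.0
    if not _WEIGHT_TOKEN_RE.match(expr):
        raise TraitConfigError(f"disallowed characters in weight expression {expr!r}")
    namespace = {
        name: fn(comp, feats)
        for name, fn in _SELECTOR_FIELDS.items()
        if name != "class"
    }
    try:
        return float(eval(expr, {"__builtins__": {}}, namespace))  # noqa: S307
    except Exception as exc:
        raise TraitConfigError(f"bad weight expression {expr!r}: {exc}") from exc


@dataclass(frozen=True)
class TraitTerm:
    """One (selector, weight) term of a trait numerator or denominator."""

    selector: str
    weight: str | float = 1.0


@dataclass(frozen=True)
class TraitDefinition:
    """Definition of a direct or derived glycan trait.

    Direct traits are total-area-normalized relative abundances of a
    single composition. Derived traits are weighted ratios
    ``sum_num(w * abundance) / (scale * sum_den(abundance))``.
    """

    trait_id: str
    platform: str  # "UHPLC-FD" or "MALDI-MS"
    kind: str  # "direct" or "derived"
    numerator: tuple[TraitTerm, ...]
    denominator: tuple[TraitTerm, ...] = (TraitTerm("*"),)
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("direct", "derived"):
            raise TraitConfigError(f"unknown trait kind {self.kind!r}")
        if self.kind == "direct" and len(self.numerator) != 1:
            raise TraitConfigError("direct traits must have a single-composition numerator")
        if self.scale == 0:
            raise TraitConfigError("scale must be nonzero")


@dataclass
class PhenotypeMatrix:
    """Samples x traits value matrix with covariates alongside.

    ``values`` columns are trait IDs (composition codes for direct peak
    matrices); ``covariates`` is indexed like ``values`` and may carry
    age, sex, batch and case status.
    """

    values: pd.DataFrame
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.covariates is not None and not self.values.index.equals(
            self.covariates.index
        ):
            raise ValueError("values and covariates must share the sample index")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def trait_ids(self) -> list[str]:
        return list(self.values.columns)


def total_area_normalize(peaks: pd.DataFrame) -> pd.DataFrame:
    """Normalize each sample's peak abundances to sum to one.

    Samples whose total is zero get missing values (no signal cannot be
    turned into composition).
    """
    totals = peaks.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("total-area normalization: %d sample(s) with zero total", int(zero.sum()))
    out = peaks.div(totals.where(~zero), axis=0)
    return out


def evaluate_derived_trait(
    defn: TraitDefinition,
    peaks: PhenotypeMatrix | pd.DataFrame,
    overrides: Mapping[str, GlycanFeatures] | None = None,
) -> pd.Series:
    """Evaluate one trait over a direct-peak abundance matrix.

    Peak columns must be parseable composition codes. Zero denominators
    yield missing values (logged), never zeros. A numerator selector
    matching no peak gives 0 for all samples.
    """
    table = peaks.values if isinstance(peaks, PhenotypeMatrix) else peaks
    comps = {}
    feats = {}
    for col in table.columns:
        comps[col] = parse_composition(str(col))
        feats[col] = classify_glycan(comps[col], overrides)

    if defn.kind == "direct":
        sel = defn.numerator[0].selector
        matched = [c for c in table.columns if _match_selector(sel, comps[c], feats[c])]
        if not matched:
            raise TraitConfigError(
                f"direct trait {defn.trait_id!r}: peak {sel!r} not in matrix"
            )
        if len(matched) > 1:
            raise TraitConfigError(
                f"direct trait {defn.trait_id!r}: selector matches {len(matched)} peaks"
            )
        rel = total_area_normalize(table)
        out = rel[matched[0]].rename(defn.trait_id)
        return out

    def _is_bare_code(sel: str) -> bool:
        sel = sel.strip()
        return sel != "*" and "&" not in sel and _CLAUSE_RE.match(sel) is None

    def _accumulate(terms: Iterable[TraitTerm]) -> pd.Series:
        acc = pd.Series(0.0, index=table.index)
        for term in terms:
            matched = False
            for col in table.columns:
                if _match_selector(term.selector, comps[col], feats[col]):
                    matched = True
                    w = _eval_weight(term.weight, comps[col], feats[col])
                    acc = acc + w * table[col]
            # an explicitly named peak must exist; feature selectors may
            # legitimately match nothing (empty sum)
            if not matched and _is_bare_code(term.selector):
                raise TraitConfigError(
                    f"trait {defn.trait_id!r}: referenced peak {term.selector!r} "
                    "not in matrix"
                )
        return acc

    num = _accumulate(defn.numerator)
    den = _accumulate(defn.denominator)
    den = defn.scale * den
    zero = den == 0
    if zero.any():
        logger.warning(
            "trait %s: zero denominator for %d sample(s); values set missing",
            defn.trait_id,
            int(zero.sum()),
        )
    out = num / den.where(~zero)
    return out.rename(defn.trait_id)


def load_trait_definitions(path: str) -> list[TraitDefinition]:
    """Read trait definitions from TSV (trait_id, platform, kind,
    numerator, denominator, scale) or JSON.

    Numerator/denominator cells are ``;``-separated ``selector:weight``
    entries; the weight part is optional (default 1).
    """
    import json
    from pathlib import Path

    text = Path(path).read_text()
    if path.endswith(".json"):
        raw = json.loads(text)
        rows = raw if isinstance(raw, list) else raw["traits"]
    else:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        rows = df.to_dict("records")
    defs = []
    for row in rows:
        defs.append(
            TraitDefinition(
                trait_id=str(row["trait_id"]),
                platform=str(row["platform"]),
                kind=str(row["kind"]),
                numerator=_parse_terms(row["numerator"]),
                denominator=_parse_terms(row.get("denominator") or "*"),
                scale=float(row.get("scale") or 1.0),
            )
        )
    return defs


def _parse_terms(raw: object) -> tuple[TraitTerm, ...]:
    if isinstance(raw, (list, tuple)):
        return tuple(
            TraitTerm(t["selector"], t.get("weight", 1.0)) if isinstance(t, dict) else TraitTerm(*t)
            for t in raw
        )
    terms = []
    for entry in str(raw).split(";"):
        entry = entry.strip()
        if not entry:
            continue
        if ":" in entry:
            sel, w = entry.rsplit(":", 1)
            terms.append(TraitTerm(sel.strip(), w.strip()))
        else:
            terms.append(TraitTerm(entry))
    if not terms:
        raise TraitConfigError(f"no terms in {raw!r}")
    return tuple(terms)


# ---------------------------------------------------------------------------
# Phenotype preprocessing
# ---------------------------------------------------------------------------

def residualize_covariates(y: np.ndarray, covars: np.ndarray) -> np.ndarray:
    """OLS residuals of ``y`` on a full-rank covariate matrix (with intercept).

    Raises ``ValueError`` on a rank-deficient covariate matrix or when
    n does not exceed the number of covariates.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(covars, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if y.shape[0] != n:
        raise ValueError("y and covars have different lengths")
    if n <= k:
        raise ValueError(f"need n > {k} covariates, got n={n}")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("rank-deficient covariate matrix")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def rank_inverse_normal(y: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offset (ties averaged).

    Maps value with rank r (1-based, average ranks for ties) to
    ``ndtri((r - c) / (n - 2c + 1))`` with c = ``offset``.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(y == y[0]):
        raise ValueError("constant trait cannot be rank-transformed")
    r = rankdata(y, method="average")
    q = (r - offset) / (n - 2.0 * offset + 1.0)
    return ndtri(q)


def center_by_batch(y: np.ndarray, batch: Sequence) -> np.ndarray:
    """Subtract per-batch means. A plain stand-in for published empirical
    Bayes batch correction (ComBat), which is deliberately not
    reimplemented here."""
    y = np.asarray(y, dtype=float)
    batch = np.asarray(batch)
    out = y.copy()
    for b in np.unique(batch):
        mask = batch == b
        out[mask] -= out[mask].mean()
    return out
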