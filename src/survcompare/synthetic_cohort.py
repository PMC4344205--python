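"""Synthetic breast-cancer-like survival cohorts with known ground truth.

Generates cohorts shaped like the METABRIC resource that motivates this
package: a table of categorical clinical covariates, a high-dimensional
continuous gene-expression matrix with a small planted informative subset,
right-censored follow-up (``day``/``status``), and a molecular subtype label
derived from the informative genes (a stand-in for a PAM50-style composite).

The survival model is a proportional-hazards Weibull (exponential by
default): the log hazard is a sum of clinical level effects, linear effects
of standardized informative-gene expression, and optional pairwise products
of informative genes.  The interaction terms plant a purely non-linear
signal — each product is marginally uncorrelated with its factors — so tree
ensembles have something a main-effects linear model cannot represent.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "Cohort",
    "CohortSpecError",
    "CohortParseError",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "CLINICAL_COVARIATES",
    "SUBTYPE_LEVELS",
]


class CohortSpecError(ValueError):
    """A cohort specification violated an invariant; names the field."""


class CohortParseError(ValueError):
    """A cohort file could not be parsed; carries row/column location."""


# Catalogue of sampled clinical covariates: levels follow the standard
# categorical codings used for breast-cancer registries (age bands, tumour
# size in mm ranges, positive-node groups, grade, receptor status, adjuvant
# treatment combinations).  ``ordered`` marks covariates with a natural
# ordinal scale.  Probabilities are fixed, roughly realistic marginals.
CLINICAL_COVARIATES: dict[str, dict] = {
    "age_at_diagnosis": {
        "levels": ["0-39", "39-54", "54-69", "69-84", "84-100"],
        "ordered": True,
        "probs": [0.08, 0.30, 0.37, 0.21, 0.04],
    },
    "size": {
        "levels": ["0-20", "20-50", "50-180"],
        "ordered": True,
        "probs": [0.42, 0.48, 0.10],
    },
    "lymph_nodes_positive": {
        "levels": ["0", "1", "2-3", "4-5", "6-9", ">=10"],
        "ordered": True,
        "probs": [0.48, 0.15, 0.15, 0.09, 0.07, 0.06],
    },
    "grade": {
        "levels": ["1", "2", "3"],
        "ordered": True,
        "probs": [0.14, 0.44, 0.42],
    },
    "ER_Expr": {
        "levels": ["+", "-"],
        "ordered": False,
        "probs": [0.76, 0.24],
    },
    "treatment": {
        "levels": ["NONE", "HT", "RT", "CT", "HT/RT", "HT/CT", "RT/CT", "HT/RT/CT"],
        "ordered": False,
        "probs": [0.10, 0.18, 0.16, 0.08, 0.22, 0.08, 0.08, 0.10],
    },
}

# Composite covariates computed (not sampled): a Nottingham-Prognostic-Index
# style risk composite of size/nodes/grade, and the expression-derived
# subtype label.
NPI_LEVELS = ["low", "intermediate", "high"]
SUBTYPE_LEVELS = ["LumA", "LumB", "Her2", "Basal", "Normal"]
SUBTYPE_COLUMN = "Pam50_subtype"


def _default_clinical_effects() -> dict[str, float]:
    # Log-hazard contributions for adverse clinical levels; directions follow
    # standard breast-cancer prognosis (higher grade/size/nodal burden and
    # ER-negativity increase hazard).
    return {
        "grade=1": -0.40,
        "grade=3": 0.55,
        "size=20-50": 0.25,
        "size=50-180": 0.70,
        "lymph_nodes_positive=2-3": 0.30,
        "lymph_nodes_positive=4-5": 0.55,
        "lymph_nodes_positive=6-9": 0.80,
        "lymph_nodes_positive=>=10": 1.10,
        "ER_Expr=-": 0.45,
        "age_at_diagnosis=69-84": 0.20,
        "age_at_diagnosis=84-100": 0.60,
    }


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Defaults define a planted-signal benchmark cohort: 500 patients,
    200 genes of which 8 carry alternating-sign linear effects (|coef| 0.6
    per standardized unit) and four disjoint pairs carry product
    interactions (coef 0.8) — the purely non-linear share of the signal.
    Clinical level effects follow realistic breast-cancer prognosis
    (grade-3, large-size and node-positive hazard ratios of roughly 1.7 to
    3).  The baseline event hazard of 1/3000 per day puts the median event
    time near 5.7 years at the reference hazard, and the dropout hazard of
    1/5000 per day censors roughly 30% of patients within five years, with
    an administrative cutoff at 20 years.
    """

    n_patients: int = 500
    n_genes: int = 200
    n_informative_genes: int = 8
    clinical_effects: Mapping[str, float] = field(default_factory=_default_clinical_effects)
    gene_effects: Sequence[float] | None = None
    interaction_strength: float = 0.8
    baseline_hazard: float = 1.0 / 3000.0
    weibull_shape: float = 1.0
    censor_dropout_rate: float = 1.0 / 5000.0
    admin_end_day: float = 7300.0
    missing_clinical_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_patients", "n_genes", "n_informative_genes"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise CohortSpecError(f"{name} must be a positive integer, got {v!r}")
        if self.n_informative_genes > self.n_genes:
            raise CohortSpecError(
                "n_informative_genes must not exceed n_genes "
                f"({self.n_informative_genes} > {self.n_genes})"
            )
        for name in ("baseline_hazard", "weibull_shape"):
            if getattr(self, name) <= 0:
                raise CohortSpecError(f"{name} must be > 0")
        for name in ("censor_dropout_rate", "missing_clinical_rate", "admin_end_day"):
            if getattr(self, name) < 0:
                raise CohortSpecError(f"{name} must be >= 0")
        if self.missing_clinical_rate >= 1:
            raise CohortSpecError("missing_clinical_rate must be < 1")
        if self.gene_effects is not None and len(self.gene_effects) != self.n_informative_genes:
            raise CohortSpecError(
                "gene_effects must have length n_informative_genes "
                f"({len(self.gene_effects)} != {self.n_informative_genes})"
            )
        valid = {
            f"{cov}={lv}"
            for cov, info in CLINICAL_COVARIATES.items()
            for lv in info["levels"]
        }
        for key in self.clinical_effects:
            if key not in valid:
                raise CohortSpecError(f"clinical_effects key {key!r} is not a known covariate=level")

    def resolved_gene_effects(self) -> np.ndarray:
        if self.gene_effects is not None:
            return np.asarray(self.gene_effects, dtype=float)
        signs = np.where(np.arange(self.n_informative_genes) % 2 == 0, 1.0, -1.0)
        return 0.6 * signs


@dataclass
class Cohort:
    """A generated cohort: clinical table, expression matrix, follow-up, truth."""

    patient_ids: list[str]
    clinical: pd.DataFrame
    expression: pd.DataFrame
    day: np.ndarray
    status: np.ndarray  # "dead" / "alive"
    truth: dict
    spec: CohortSpec | None = None

    def __len__(self) -> int:
        return len(self.patient_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.patient_ids == other.patient_ids
            and self.clinical.equals(other.clinical)
            and self.expression.equals(other.expression)
            and np.array_equal(self.day, other.day)
            and np.array_equal(self.status, other.status)
            and self.truth == other.truth
        )


def _clinical_dtype(levels: Sequence[str], ordered: bool) -> pd.CategoricalDtype:
    return pd.CategoricalDtype(categories=list(levels), ordered=ordered)


def _sample_clinical(rng: np.random.Generator, n: int) -> pd.DataFrame:
    cols = {}
    for cov, info in CLINICAL_COVARIATES.items():
        draws = rng.choice(len(info["levels"]), size=n, p=info["probs"])
        cols[cov] = pd.Categorical.from_codes(
            draws, dtype=_clinical_dtype(info["levels"], info["ordered"])
        )
    df = pd.DataFrame(cols)
    # NPI-like composite of size, nodal burden and grade.
    score = (
        df["size"].cat.codes.to_numpy()
        + df["lymph_nodes_positive"].cat.codes.to_numpy() // 2
        + df["grade"].cat.codes.to_numpy()
    )
    npi_codes = np.digitize(score, [2, 4])  # 0..1 low, 2..3 intermediate, 4+ high
    df["NPI"] = pd.Categorical.from_codes(npi_codes, dtype=_clinical_dtype(NPI_LEVELS, True))
    return df


def _subtype_from_genes(z1: np.ndarray, z2: np.ndarray) -> pd.Categorical:
    codes = np.select(
        [
            (np.abs(z1) < 0.3) & (np.abs(z2) < 0.3),
            (z1 >= 0) & (z2 >= 0),
            (z1 >= 0) & (z2 < 0),
            (z1 < 0) & (z2 >= 0),
        ],
        [
            SUBTYPE_LEVELS.index("Normal"),
            SUBTYPE_LEVELS.index("Basal"),
            SUBTYPE_LEVELS.index("Her2"),
            SUBTYPE_LEVELS.index("LumB"),
        ],
        default=SUBTYPE_LEVELS.index("LumA"),
    )
    return pd.Categorical.from_codes(codes, dtype=_clinical_dtype(SUBTYPE_LEVELS, False))


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a cohort from the planted proportional-hazards model.

    Event times follow a Weibull with shape ``weibull_shape`` (exponential at
    the default shape 1) whose log hazard is the sum of the configured
    clinical, gene and interaction effects.  The observed ``day`` is the
    minimum of the event time, an exponential dropout time and the
    administrative cutoff; ``status`` is ``"dead"`` only when the event comes
    first.  Identical spec + seed yields a bit-identical cohort.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_patients, spec.n_genes

    clinical = _sample_clinical(rng, n)

    # Expression on a log-intensity-like scale.  Background genes are
    # unimodal Gaussians; informative genes are two-component mixtures
    # (modes at mu +/- 1.2 sd), emulating the bimodal, subtype-driven
    # distributions typical of prognostic marker genes in breast tumours.
    mu = rng.normal(8.0, 1.0, size=g)
    sd = rng.uniform(0.5, 1.5, size=g)
    expr = rng.normal(mu, sd, size=(n, g))
    gene_names = [f"G{j:05d}" for j in range(g)]

    informative = np.sort(rng.choice(g, size=spec.n_informative_genes, replace=False))
    coefs = spec.resolved_gene_effects()
    mode = rng.choice([-1.0, 1.0], size=(n, spec.n_informative_genes))
    expr[:, informative] = (
        mu[informative]
        + 1.2 * sd[informative] * mode
        + 0.6 * sd[informative] * rng.normal(size=(n, spec.n_informative_genes))
    )
    expression = pd.DataFrame(expr, columns=gene_names)
    # Standardize by the mixture's theoretical moments: var = (1.2^2 + 0.6^2) sd^2.
    mix_sd = sd[informative] * np.sqrt(1.2**2 + 0.6**2)
    z = (expr[:, informative] - mu[informative]) / mix_sd

    eta = np.zeros(n)
    for key, effect in spec.clinical_effects.items():
        cov, level = key.split("=", 1)
        eta += np.where(clinical[cov].to_numpy() == level, float(effect), 0.0)
    eta += z @ coefs
    pairs = [(2 * i, 2 * i + 1) for i in range(spec.n_informative_genes // 2)]
    if spec.interaction_strength != 0.0:
        for a, b in pairs:
            eta += spec.interaction_strength * z[:, a] * z[:, b]

    # Subtype label: a coarse composite of the first informative genes.
    clinical[SUBTYPE_COLUMN] = _subtype_from_genes(z[:, 0], z[:, 1 % z.shape[1]])

    # Inverse-CDF draw: cumulative hazard (b t)^k e^eta equated to Exp(1).
    e = rng.exponential(1.0, size=n)
    t_event = (e * np.exp(-eta)) ** (1.0 / spec.weibull_shape) / spec.baseline_hazard
    if spec.censor_dropout_rate > 0:
        t_drop = rng.exponential(1.0 / spec.censor_dropout_rate, size=n)
    else:
        t_drop = np.full(n, np.inf)
    admin = spec.admin_end_day if spec.admin_end_day > 0 else np.inf
    day = np.minimum(np.minimum(t_event, t_drop), admin)
    status = np.where((t_event <= t_drop) & (t_event <= admin), "dead", "alive")

    if spec.missing_clinical_rate > 0:
        for cov in CLINICAL_COVARIATES:
            mask = rng.random(n) < spec.missing_clinical_rate
            col = clinical[cov].copy()
            col[mask] = np.nan
            clinical[cov] = col

    truth = {
        "informative_genes": [gene_names[j] for j in informative],
        "gene_effects": [float(c) for c in coefs],
        "interaction_pairs": [
            [gene_names[informative[a]], gene_names[informative[b]]] for a, b in pairs
        ],
        "interaction_strength": float(spec.interaction_strength),
        "eta": [float(v) for v in eta],
    }
    return Cohort(
        patient_ids=[f"P{i:05d}" for i in range(n)],
        clinical=clinical,
        expression=expression,
        day=day.astype(float),
        status=status.astype(object),
        truth=truth,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# CSV round-trip.  Three delimited tables plus a JSON sidecar holding the
# truth record, the spec, and the categorical level sets (so dtypes survive).
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    clin = cohort.clinical.copy()
    clin.insert(0, "patient_id", cohort.patient_ids)
    clin.to_csv(path / "clinical.csv", index=False)
    expr = cohort.expression.copy()
    expr.insert(0, "patient_id", cohort.patient_ids)
    # %.17g guarantees bit-exact float round-trips through text
    expr.to_csv(path / "expression.csv", index=False, float_format="%.17g")
    pd.DataFrame(
        {"patient_id": cohort.patient_ids, "day": cohort.day, "status": cohort.status}
    ).to_csv(path / "followup.csv", index=False, float_format="%.17g")
    levels = {
        col: {
            "levels": [str(c) for c in cohort.clinical[col].cat.categories],
            "ordered": bool(cohort.clinical[col].cat.ordered),
        }
        for col in cohort.clinical.columns
    }
    sidecar = {
        "truth": cohort.truth,
        "spec": dataclasses.asdict(cohort.spec) if cohort.spec is not None else None,
        "clinical_levels": levels,
    }
    (path / "truth.json").write_text(json.dumps(sidecar, indent=1))


def read_cohort(path: str | Path) -> Cohort:
    path = Path(path)
    sidecar = json.loads((path / "truth.json").read_text())
    clin_raw = pd.read_csv(path / "clinical.csv", dtype=str)
    patient_ids = clin_raw.pop("patient_id").tolist()
    clinical = pd.DataFrame(index=clin_raw.index)
    for col, info in sidecar["clinical_levels"].items():
        if col not in clin_raw.columns:
            raise CohortParseError(f"clinical.csv is missing column {col!r}")
        clinical[col] = pd.Categorical(
            clin_raw[col], dtype=_clinical_dtype(info["levels"], info["ordered"])
        )
    expression = pd.read_csv(path / "expression.csv", float_precision="round_trip")
    expression = expression.drop(columns=["patient_id"])
    follow = pd.read_csv(
        path / "followup.csv", dtype={"patient_id": str, "status": str},
        float_precision="round_trip",
    )
    day_raw = follow["day"]
    try:
        day = pd.to_numeric(day_raw, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError):
        bad = pd.to_numeric(day_raw, errors="coerce")
        row = int(bad[bad.isna() & day_raw.notna()].index[0])
        raise CohortParseError(
            f"followup.csv: non-numeric value {day_raw.iloc[row]!r} "
            f"in column 'day', row {row + 2}"
        ) from None
    status = follow["status"].to_numpy(dtype=object)
    bad_status = ~np.isin(status, ["dead", "alive"])
    if bad_status.any():
        row = int(np.argmax(bad_status))
        raise CohortParseError(
            f"followup.csv: invalid status {status[row]!r} in column 'status', row {row + 2}"
        )
    spec = CohortSpec(**sidecar["spec"]) if sidecar["spec"] is not None else None
    return Cohort(
        patient_ids=patient_ids,
        clinical=clinical,
        expression=expression,
        day=day,
        status=status,
        truth=sidecar["truth"],
        spec=spec,
    )
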