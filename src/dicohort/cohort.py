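"""Discrete cohort data model.

A cohort is an N-patients x L-variables matrix of categorical states.  Every
variable carries an explicit alphabet (ordered list of state labels), so the
matrix can be fed directly into the Potts-model machinery in
:mod:`dicohort.dca`.  Continuous clinical covariates (age, BMI, blood
pressure, disease duration, ...) are quantized into decade-wide bins before
entering the matrix; the raw values are retained alongside for descriptive
summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableSchema",
    "PatientProfile",
    "DiscreteCohort",
    "genotype_states",
    "bin_decades",
    "decade_states",
    "label_response",
    "read_cohort",
    "read_schema_config",
    "summarize_treatment_lines",
    "summarize_phenotypes",
]

RESPONDER = "Res"
NON_RESPONDER = "NonRes"
RESPONSE_CUTOFF = 7.0  # HbA1c (%) at or below which a patient is a responder

VARIABLE_KINDS = ("binned-continuous", "categorical", "genotype", "drug", "response")

DRUG_ABSENT = "absent"
DRUG_PRESENT = "present"

DEFAULT_MISSING = "NA"


def genotype_states(ref: str, alt: str) -> tuple[str, str, str]:
    """Canonical genotype alphabet for a biallelic SNP: hom-ref, het, hom-alt."""
    return (f"{ref}/{ref}", f"{ref}/{alt}", f"{alt}/{alt}")


@dataclass(frozen=True)
class VariableSchema:
    """Declaration of one cohort variable: its kind and state alphabet.

    Parameters
    ----------
    name
        Column identifier.
    kind
        One of ``binned-continuous``, ``categorical``, ``genotype``, ``drug``
        or ``response``.
    states
        Ordered alphabet of state labels (size :math:`q_i \\ge 2`).  The last
        state is used as the zero-coupling reference (gauge) state downstream.
    missing_label
        State label reserved for missing / not-applicable cells, or ``None``
        if the variable cannot be missing.  When set it must be a member of
        ``states``.
    line
        Therapy-line tag for drug variables (e.g. ``"FLT"``).
    alleles
        ``(ref, alt)`` pair for genotype variables.
    """

    name: str
    kind: str
    states: tuple[str, ...]
    missing_label: str | None = None
    line: str | None = None
    alleles: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in VARIABLE_KINDS:
            raise ValueError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        object.__setattr__(self, "states", tuple(str(s) for s in self.states))
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"duplicate state labels in variable {self.name!r}")
        if len(self.states) < 2:
            raise ValueError(
                f"variable {self.name!r} has alphabet size {len(self.states)} < 2"
            )
        if self.missing_label is not None and self.missing_label not in self.states:
            raise ValueError(
                f"missing_label {self.missing_label!r} not in states of {self.name!r}"
            )
        if self.kind == "genotype":
            if self.alleles is None:
                raise ValueError(f"genotype variable {self.name!r} requires alleles")
            expected = genotype_states(*self.alleles)
            core = tuple(s for s in self.states if s != self.missing_label)
            if core != expected:
                raise ValueError(
                    f"genotype variable {self.name!r} must have states "
                    f"{expected} (plus optional missing), got {core}"
                )
        if self.kind == "response" and tuple(
            s for s in self.states if s != self.missing_label
        ) != (RESPONDER, NON_RESPONDER):
            raise ValueError(
                f"response variable {self.name!r} must have states "
                f"({RESPONDER!r}, {NON_RESPONDER!r})"
            )

    @property
    def q(self) -> int:
        """Alphabet size."""
        return len(self.states)

    def index_of(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(
                f"state {state!r} is not in the alphabet of variable {self.name!r}"
            ) from None


@dataclass(frozen=True)
class PatientProfile:
    """One patient's row: an ordered vector of state labels."""

    patient_id: str
    states: tuple[str, ...]


class DiscreteCohort:
    """A fully encoded cohort: schema plus an N x L state-label matrix.

    ``data`` is a :class:`pandas.DataFrame` indexed by patient id whose cells
    are state labels.  ``raw`` optionally holds the continuous source columns
    (same index) used by :func:`summarize_phenotypes`.
    """

    def __init__(
        self,
        schema: Sequence[VariableSchema],
        data: pd.DataFrame,
        raw: pd.DataFrame | None = None,
    ) -> None:
        self.schema = list(schema)
        names = [v.name for v in self.schema]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in schema")
        missing_cols = [n for n in names if n not in data.columns]
        if missing_cols:
            raise ValueError(f"data lacks declared columns: {missing_cols}")
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate patient ids: {dupes}")
        if len(data) < 1:
            raise ValueError("cohort must contain at least one patient")
        self.data = data.loc[:, names].astype(str)
        self.raw = raw
        self._validate_states()

    # -- basic accessors ---------------------------------------------------

    def _validate_states(self) -> None:
        for var in self.schema:
            observed = set(self.data[var.name].unique())
            extra = observed - set(var.states)
            if extra:
                raise ValueError(
                    f"variable {var.name!r} contains labels outside its "
                    f"alphabet: {sorted(extra)}"
                )

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def n_variables(self) -> int:
        return len(self.schema)

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.schema]

    def variable(self, name: str) -> VariableSchema:
        for var in self.schema:
            if var.name == name:
                return var
        raise KeyError(f"no variable named {name!r}")

    def variables_of_kind(self, kind: str) -> list[VariableSchema]:
        return [v for v in self.schema if v.kind == kind]

    @property
    def response_variable(self) -> VariableSchema:
        resp = self.variables_of_kind("response")
        if len(resp) != 1:
            raise ValueError(f"expected exactly one response variable, got {len(resp)}")
        return resp[0]

    def profiles(self) -> Iterator[PatientProfile]:
        for pid, row in self.data.iterrows():
            yield PatientProfile(str(pid), tuple(row))

    def codes(self) -> np.ndarray:
        """Integer encoding (N, L): each cell replaced by its state index."""
        cols = []
        for var in self.schema:
            lut = {s: i for i, s in enumerate(var.states)}
            cols.append(self.data[var.name].map(lut).to_numpy(dtype=np.int64))
        return np.column_stack(cols)

    def decode(self, codes: np.ndarray, patient_ids: Sequence[str] | None = None) -> "DiscreteCohort":
        """Inverse of :meth:`codes` — rebuild a cohort from integer states."""
        codes = np.asarray(codes)
        if patient_ids is None:
            patient_ids = [f"P{i:04d}" for i in range(codes.shape[0])]
        data = pd.DataFrame(
            {
                var.name: [var.states[c] for c in codes[:, j]]
                for j, var in enumerate(self.schema)
            },
            index=pd.Index(patient_ids, name=self.data.index.name or "patient_id"),
        )
        return DiscreteCohort(self.schema, data)

    def drop_variables(self, names: Iterable[str]) -> "DiscreteCohort":
        drop = set(names)
        schema = [v for v in self.schema if v.name not in drop]
        return DiscreteCohort(schema, self.data.drop(columns=list(drop)), raw=self.raw)

    def subset_patients(self, patient_ids: Sequence) -> "DiscreteCohort":
        raw = self.raw.loc[patient_ids] if self.raw is not None else None
        return DiscreteCohort(self.schema, self.data.loc[patient_ids], raw=raw)


# -- encoding primitives ---------------------------------------------------


def bin_decades(value: float) -> str:
    """Decade-span bin label for a non-negative value.

    Bins are half-open: ``[10k, 10(k+1))``, so 60.0 falls in ``[60,70)``.
    """
    v = float(value)
    if not math.isfinite(v) or v < 0:
        raise ValueError(f"bin_decades requires a finite non-negative value, got {value}")
    k = int(v // 10)
    return f"[{10 * k},{10 * (k + 1)})"


def decade_states(lo: float, hi: float) -> tuple[str, ...]:
    """All decade bins touching the interval [lo, hi]."""
    if hi < lo:
        raise ValueError("hi < lo")
    return tuple(
        f"[{10 * k},{10 * (k + 1)})" for k in range(int(lo // 10), int(hi // 10) + 1)
    )


def decade_start(label: str) -> int:
    """Left edge of a decade-bin label (for ordering assertions)."""
    return int(label[1:].split(",")[0])


def label_response(hba1c: float) -> str:
    """Treat-to-target classification: responder iff HbA1c <= 7 %."""
    v = float(hba1c)
    if not math.isfinite(v) or v <= 0:
        raise ValueError(f"HbA1c must be a finite positive percentage, got {hba1c}")
    return RESPONDER if v <= RESPONSE_CUTOFF else NON_RESPONDER


def _normalize_genotype_cell(
    cell: str, var: VariableSchema
) -> str:
    """Map an allele-pair string onto the canonical genotype alphabet.

    Allele pairs are unordered: ``C/A`` and ``A/C`` both denote the
    heterozygote of a SNP with alleles A and C.
    """
    cell = cell.strip()
    if cell == "" or cell.upper() in {"NA", "NAN", "./."}:
        if var.missing_label is None:
            raise ValueError(
                f"missing genotype in {var.name!r} but no missing_label declared"
            )
        return var.missing_label
    if cell in var.states:
        return cell
    parts = cell.replace("|", "/").split("/")
    if len(parts) != 2:
        raise ValueError(f"cell {cell!r} in {var.name!r} is not an allele pair")
    ref, alt = var.alleles  # type: ignore[misc]
    order = {ref: 0, alt: 1}
    try:
        a, b = sorted(parts, key=lambda x: order[x])
    except KeyError:
        raise ValueError(
            f"cell {cell!r} in {var.name!r} uses alleles outside {var.alleles}"
        ) from None
    return f"{a}/{b}"


# -- reading raw tables ----------------------------------------------------

_FALSY_DRUG = {"", "0", "0.0", "no", "none", "absent", "false"}


def read_schema_config(path_or_mapping) -> dict:
    """Load a schema config from a YAML file path or pass a mapping through."""
    if isinstance(path_or_mapping, Mapping):
        return dict(path_or_mapping)
    with open(path_or_mapping) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("schema config must be a mapping")
    return cfg


def read_cohort(path, schema_config) -> DiscreteCohort:
    """Read a delimited text table and encode it against a schema config.

    The config declares, per column, its ``kind`` and any encoding rule
    (allele pair for genotypes, explicit states for categoricals, decade
    binning for continuous columns, therapy line for drugs).  The response
    column may be given directly (states Res/NonRes) or derived from an
    HbA1c column via the treat-to-target cutoff.
    """
    cfg = read_schema_config(schema_config)
    sep = cfg.get("sep")
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     dtype=str, keep_default_na=False)
    id_col = cfg.get("patient_id")
    if id_col is not None:
        if id_col not in df.columns:
            raise ValueError(f"declared patient_id column {id_col!r} absent from header")
        df = df.set_index(id_col)
    else:
        df.index = pd.Index([f"P{i:04d}" for i in range(len(df))], name="patient_id")
    if df.index.has_duplicates:
        raise ValueError("duplicate patient_id values in input")

    schema: list[VariableSchema] = []
    encoded: dict[str, list[str]] = {}
    raw_cols: dict[str, np.ndarray] = {}

    for spec in cfg.get("variables", []):
        name = spec["name"]
        kind = spec["kind"]
        source = spec.get("source", name)
        if kind != "response" and source not in df.columns:
            raise ValueError(f"declared column {source!r} absent from header")
        missing = spec.get("missing_label", DEFAULT_MISSING)

        if kind == "genotype":
            alleles = tuple(spec["alleles"])
            var = VariableSchema(
                name, "genotype", genotype_states(*alleles) + (missing,),
                missing_label=missing, alleles=alleles,
            )
            encoded[name] = [_normalize_genotype_cell(c, var) for c in df[source]]
        elif kind == "binned-continuous":
            vals = pd.to_numeric(df[source].replace("", np.nan))
            raw_cols[name] = vals.to_numpy(dtype=float)
            labels = [missing if pd.isna(v) else bin_decades(v) for v in vals]
            present = sorted({l for l in labels if l != missing}, key=decade_start)
            states = tuple(present) + ((missing,) if missing in labels else ())
            var = VariableSchema(name, kind, states,
                                 missing_label=missing if missing in labels else None)
            encoded[name] = labels
        elif kind == "categorical":
            declared = spec.get("states")
            labels = [c.strip() if c.strip() else missing for c in df[source]]
            if declared is None:
                uniq = sorted({l for l in labels if l != missing})
                states = tuple(uniq) + ((missing,) if missing in labels else ())
            else:
                unknown = {l for l in labels if l != missing} - set(map(str, declared))
                if unknown:
                    raise ValueError(
                        f"column {name!r} contains undeclared labels: {sorted(unknown)}"
                    )
                states = tuple(map(str, declared)) + (
                    (missing,) if missing in labels else ()
                )
            var = VariableSchema(name, kind, states,
                                 missing_label=missing if missing in labels else None)
            encoded[name] = labels
        elif kind == "drug":
            thresholds = spec.get("dose_thresholds")
            cells = [c.strip() for c in df[source]]
            if thresholds is None:
                labels = [
                    DRUG_ABSENT if c.lower() in _FALSY_DRUG else DRUG_PRESENT
                    for c in cells
                ]
                states: tuple[str, ...] = (DRUG_ABSENT, DRUG_PRESENT)
            else:
                low_hi = float(thresholds)
                labels = []
                for c in cells:
                    if c.lower() in _FALSY_DRUG:
                        labels.append(DRUG_ABSENT)
                    else:
                        dose = float(c)
                        labels.append("low" if dose < low_hi else "high")
                states = (DRUG_ABSENT, "low", "high")
            var = VariableSchema(name, "drug", states, line=spec.get("line"))
            encoded[name] = labels
        elif kind == "response":
            hba1c_col = spec.get("hba1c")
            if hba1c_col is not None:
                if hba1c_col not in df.columns:
                    raise ValueError(f"declared column {hba1c_col!r} absent from header")
                vals = pd.to_numeric(df[hba1c_col])
                raw_cols[hba1c_col] = vals.to_numpy(dtype=float)
                labels = [label_response(v) for v in vals]
            else:
                labels = list(df[source])
            var = VariableSchema(name, "response", (RESPONDER, NON_RESPONDER))
            encoded[name] = labels
        else:
            raise ValueError(f"unknown variable kind {kind!r}")
        schema.append(var)

    data = pd.DataFrame(encoded, index=df.index)
    raw = pd.DataFrame(raw_cols, index=df.index) if raw_cols else None
    return DiscreteCohort(schema, data, raw=raw)


# -- descriptive summaries -------------------------------------------------


def summarize_treatment_lines(cohort: DiscreteCohort) -> pd.DataFrame:
    """Per-therapy-line drug usage counts and percentages.

    For each therapy line, counts patients on each drug and the percentage of
    that line's total prescriptions, rounded to one decimal.
    """
    drugs = cohort.variables_of_kind("drug")
    if not drugs:
        raise ValueError("cohort has no drug columns")
    rows = []
    by_line: dict[str, list[VariableSchema]] = {}
    for var in drugs:
        by_line.setdefault(var.line or "unspecified", []).append(var)
    for line, vars_ in by_line.items():
        counts = {
            v.name: int((cohort.data[v.name] != DRUG_ABSENT).sum()) for v in vars_
        }
        total = sum(counts.values())
        for v in vars_:
            pct = round(100.0 * counts[v.name] / total, 1) if total else float("nan")
            rows.append(
                {"line": line, "drug": v.name, "n": counts[v.name],
                 "percent": pct, "line_total": total}
            )
    return pd.DataFrame(rows)


def summarize_phenotypes(
    cohort: DiscreteCohort,
    grouping: str,
    covariates: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Group-wise N (with % of cohort) and mean +/- SD of continuous covariates.

    ``grouping`` names a schema variable; covariates are looked up in the
    cohort's retained raw (un-binned) columns.  Single-observation groups are
    flagged degenerate and report SD 0.
    """
    if grouping not in cohort.variable_names:
        raise KeyError(f"unknown grouping variable {grouping!r}")
    if covariates is None:
        covariates = list(cohort.raw.columns) if cohort.raw is not None else []
    else:
        if cohort.raw is None and covariates:
            raise ValueError("cohort retains no raw continuous columns")
        for c in covariates:
            if c not in cohort.raw.columns:
                raise KeyError(f"unknown covariate {c!r}")
    n_total = cohort.n_patients
    rows = []
    groups = cohort.data[grouping]
    for g in cohort.variable(grouping).states:
        mask = (groups == g).to_numpy()
        n = int(mask.sum())
        if n == 0:
            continue
        row: dict = {
            "group": g,
            "n": n,
            "percent": round(100.0 * n / n_total, 1),
            "degenerate": n == 1,
        }
        for c in covariates:
            vals = cohort.raw.loc[mask, c].dropna().to_numpy() if cohort.raw is not None else np.array([])
            if len(vals) == 0:
                mean, sd = float("nan"), float("nan")
            elif len(vals) == 1:
                mean, sd = float(vals[0]), 0.0
            else:
                mean, sd = float(np.mean(vals)), float(np.std(vals, ddof=1))
            row[f"{c}_mean"] = mean
            row[f"{c}_sd"] = sd
        rows.append(row)
    return pd.DataFrame(rows)
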