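"""Cohort CSV reading/writing and configuration files.

Cohorts travel as long-format CSV with columns
``patient_id,week,n_symptoms[,generator,true_state]`` — week 1-based and
contiguous per patient, counts integers in [0, trials_m], UTF-8 with LF line
endings. Reading applies the complete-case rule: a patient whose record does
not span exactly the expected number of weeks is excluded (and reported),
never silently analysed.

Configuration is YAML with two optional sections, ``analysis`` and
``simulate``; unknown keys are rejected so typos fail loudly. A fully
annotated example ships in ``docs/config_example.yaml``.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import yaml

from ._errors import ConfigError, ValidationError
from .series import SymptomSeries

REQUIRED_COLUMNS = ("patient_id", "week", "n_symptoms")
OPTIONAL_COLUMNS = ("generator", "true_state")


@dataclass
class CohortReadReport:
    """What happened while reading a cohort file."""

    n_rows: int
    n_patients_read: int
    n_patients_kept: int
    excluded: dict[str, str] = field(default_factory=dict)


def write_cohort(cohort: Sequence[SymptomSeries], path: str | Path) -> None:
    """Write a cohort as canonical long-format CSV (LF endings, UTF-8).

    Optional columns are emitted only when at least one series carries them.
    """
    if not cohort:
        raise ValidationError("cannot write an empty cohort")
    Path(path).write_text(cohort_to_csv_string(cohort), encoding="utf-8", newline="")


def read_cohort(
    path: str | Path,
    expected_T: int | None = None,
    trials_m: int = 9,
) -> tuple[list[SymptomSeries], CohortReadReport]:
    """Read a long-format cohort CSV with validation.

    Hard errors (malformed rows, counts outside [0, trials_m], duplicate
    (patient, week) pairs) raise :class:`ValidationError` with the line
    number. Patients whose weeks are not contiguous from 1, or whose length
    differs from ``expected_T`` when given, are excluded with a recorded
    reason — the complete-case rule — and the remaining patients are
    returned.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    per_patient: dict[str, dict[int, tuple[int, str | None, int | None]]] = {}
    n_rows = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file, header required") from None
        header = [h.strip() for h in header]
        if tuple(header[:3]) != REQUIRED_COLUMNS:
            raise ValidationError(
                f"{path}: header must start with "
                f"{','.join(REQUIRED_COLUMNS)}, got {','.join(header)}"
            )
        extra = header[3:]
        unknown = [h for h in extra if h not in OPTIONAL_COLUMNS]
        if unknown:
            raise ValidationError(f"{path}: unknown column(s) {unknown}")
        gen_idx = 3 + extra.index("generator") if "generator" in extra else None
        st_idx = 3 + extra.index("true_state") if "true_state" in extra else None

        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValidationError(
                    f"{path}, line {lineno}: expected {len(header)} fields, "
                    f"got {len(row)}"
                )
            pid = row[0]
            try:
                week = int(row[1])
                count = int(row[2])
            except ValueError:
                raise ValidationError(
                    f"{path}, line {lineno}: week and n_symptoms must be "
                    f"integers, got {row[1]!r}, {row[2]!r}"
                ) from None
            if week < 1:
                raise ValidationError(
                    f"{path}, line {lineno}: week must be >= 1, got {week}"
                )
            if not 0 <= count <= trials_m:
                raise ValidationError(
                    f"{path}, line {lineno}: n_symptoms {count} outside "
                    f"[0, {trials_m}]"
                )
            gen = row[gen_idx] or None if gen_idx is not None else None
            if st_idx is not None and row[st_idx] != "":
                try:
                    state: int | None = int(row[st_idx])
                except ValueError:
                    raise ValidationError(
                        f"{path}, line {lineno}: true_state must be an "
                        f"integer, got {row[st_idx]!r}"
                    ) from None
            else:
                state = None
            weeks = per_patient.setdefault(pid, {})
            if week in weeks:
                raise ValidationError(
                    f"{path}, line {lineno}: duplicate (patient, week) pair "
                    f"({pid!r}, {week})"
                )
            weeks[week] = (count, gen, state)
            n_rows += 1

    cohort: list[SymptomSeries] = []
    excluded: dict[str, str] = {}
    for pid, weeks in per_patient.items():
        T = len(weeks)
        if sorted(weeks) != list(range(1, T + 1)):
            missing = sorted(set(range(1, max(weeks) + 1)) - set(weeks))
            excluded[pid] = f"weeks not contiguous from 1 (missing {missing[:5]})"
            continue
        if expected_T is not None and T != expected_T:
            excluded[pid] = f"incomplete record: {T} weeks, expected {expected_T}"
            continue
        counts = [weeks[w][0] for w in range(1, T + 1)]
        gens = {weeks[w][1] for w in range(1, T + 1)}
        states = [weeks[w][2] for w in range(1, T + 1)]
        cohort.append(
            SymptomSeries(
                patient_id=pid,
                counts=counts,
                trials_m=trials_m,
                generator=next(iter(gens)) if len(gens) == 1 else None,
                true_states=states if all(s is not None for s in states) else None,
            )
        )
    report = CohortReadReport(
        n_rows=n_rows,
        n_patients_read=len(per_patient),
        n_patients_kept=len(cohort),
        excluded=excluded,
    )
    return cohort, report


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable analysis settings with the study defaults.

    T: required series length (complete-case rule); trials_m: symptoms per
    week; bc_threshold: BC classification cut; n_restarts/tol/max_iter: EM
    settings; seed: master seed for the EM restarts.
    """

    T: int = 104
    trials_m: int = 9
    bc_threshold: float = 0.55
    n_restarts: int = 10
    tol: float = 1e-8
    max_iter: int = 500
    seed: int = 0


@dataclass(frozen=True)
class SimulateConfig:
    """A cohort-simulation request: a mixture of generator components."""

    n_patients: int
    components: tuple[dict, ...]
    T: int = 104
    trials_m: int = 9
    seed: int = 0


@dataclass(frozen=True)
class Config:
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    simulate: SimulateConfig | None = None


_GENERATOR_PARAMS = {
    "markov_binomial": {"initial", "transition", "emission_p"},
    "smooth_severity": {"ar_phi", "innovation_sd", "baseline_logit"},
    "flatline": {"emission_p"},
    "network": {"connectivity_c", "stress_b", "gain", "noise_sd"},
}


def _check_keys(given: dict, allowed: set[str], where: str) -> None:
    unknown = sorted(set(given) - allowed)
    if unknown:
        raise ConfigError(
            f"unknown key {unknown[0]!r} in {where} "
            f"(allowed: {', '.join(sorted(allowed))})"
        )


def _parse_component(comp: dict, idx: int) -> dict:
    if not isinstance(comp, dict):
        raise ConfigError(f"simulate.components[{idx}] must be a mapping")
    _check_keys(comp, {"kind", "proportion", "params"}, f"components[{idx}]")
    if "kind" not in comp:
        raise ConfigError(f"components[{idx}]: missing required key 'kind'")
    kind = comp["kind"]
    if kind not in _GENERATOR_PARAMS:
        raise ConfigError(
            f"components[{idx}]: unknown generator kind {kind!r}"
        )
    if "proportion" not in comp:
        raise ConfigError(f"components[{idx}]: missing required key 'proportion'")
    params = comp.get("params", {}) or {}
    _check_keys(params, _GENERATOR_PARAMS[kind], f"components[{idx}].params")
    return {
        "kind": kind,
        "proportion": float(comp["proportion"]),
        "params": dict(params),
    }


def parse_config(data: dict | None) -> Config:
    """Validate a parsed configuration mapping (empty means all defaults)."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    _check_keys(data, {"analysis", "simulate"}, "configuration root")

    analysis_raw = data.get("analysis") or {}
    allowed = {f.name for f in fields(AnalysisConfig)}
    _check_keys(analysis_raw, allowed, "analysis section")
    try:
        analysis = replace(AnalysisConfig(), **analysis_raw)
    except TypeError as exc:
        raise ConfigError(f"invalid analysis settings: {exc}") from exc
    if analysis.bc_threshold <= 0:
        raise ConfigError("bc_threshold must be positive")

    simulate = None
    if "simulate" in data and data["simulate"] is not None:
        sim_raw = dict(data["simulate"])
        _check_keys(
            sim_raw,
            {"n_patients", "T", "trials_m", "seed", "components", "kind", "params"},
            "simulate section",
        )
        if "n_patients" not in sim_raw:
            raise ConfigError("simulate section: missing required key 'n_patients'")
        if "components" in sim_raw:
            comps = tuple(
                _parse_component(c, i) for i, c in enumerate(sim_raw["components"])
            )
        elif "kind" in sim_raw:
            comps = (
                _parse_component(
                    {
                        "kind": sim_raw["kind"],
                        "proportion": 1.0,
                        "params": sim_raw.get("params", {}),
                    },
                    0,
                ),
            )
        else:
            raise ConfigError(
                "simulate section needs either 'components' or a single 'kind'"
            )
        simulate = SimulateConfig(
            n_patients=int(sim_raw["n_patients"]),
            components=comps,
            T=int(sim_raw.get("T", 104)),
            trials_m=int(sim_raw.get("trials_m", 9)),
            seed=int(sim_raw.get("seed", 0)),
        )
    return Config(analysis=analysis, simulate=simulate)


def load_config(path: str | Path) -> Config:
    """Load and validate a YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    with open(path, encoding="utf-8") as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    return parse_config(data)


def cohort_to_csv_string(cohort: Sequence[SymptomSeries]) -> str:
    """Canonical CSV text of a cohort (used for round-trip checks)."""
    buf = _io.StringIO()
    has_gen = any(s.generator is not None for s in cohort)
    has_state = any(s.true_states is not None for s in cohort)
    cols = list(REQUIRED_COLUMNS)
    if has_gen:
        cols.append("generator")
    if has_state:
        cols.append("true_state")
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(cols)
    for s in cohort:
        for week, count in enumerate(s.counts, start=1):
            row: list = [s.patient_id, week, int(count)]
            if has_gen:
                row.append(s.generator if s.generator is not None else "")
            if has_state:
                row.append(
                    int(s.true_states[week - 1]) if s.true_states is not None else ""
                )
            writer.writerow(row)
    return buf.getvalue()
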