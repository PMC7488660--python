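"""End-to-end analysis pipeline: configuration, validation, I/O, reports.

The pipeline reads the three claims tables (persons, spells, cases), builds
the base and lookback subpopulations, computes selectivity tables for age,
qualification and income, and crude plus base-standardized incidence rates
for each configured disease, writing every result as a CSV report.  Re-runs
on identical inputs produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import incidence as inc
from .bins import FIVE_YEAR_BINS, TEN_YEAR_BINS
from .cohorts import build_cohorts, reduction_table
from .scenario import INCOME_GROUPS, QUALIFICATION_LEVELS
from .selectivity import (
    IncomeClassification,
    age_summary,
    classify_income_values,
    exclusion_by_stratum,
)
from .spells import SpellError

__all__ = ["RunConfig", "ValidationReport", "validate_inputs", "read_tables",
           "run_pipeline"]

logger = logging.getLogger(__name__)

_SEXES = {"male", "female"}
_QUALS = set(QUALIFICATION_LEVELS) | {"not_applicable"}
_INCOMES = set(INCOME_GROUPS)


@dataclass
class RunConfig:
    """Everything one analysis run needs; loadable from YAML."""

    persons_path: str
    spells_path: str
    cases_path: str
    out_dir: str
    index_year: int = 2017
    lookbacks: tuple[int, ...] = (1, 3, 5)
    diseases: tuple[str, ...] = ("MI", "stroke")
    min_age: int = 25
    income_low_bound: float = 14_000.0
    income_high_bound: float = 29_000.0
    gap_tolerance_days: int = 0
    censor_at_event: bool = False
    use_secondary_history: bool = True
    i252_full_history: bool = False
    make_plots: bool = False

    def __post_init__(self) -> None:
        self.lookbacks = tuple(int(k) for k in self.lookbacks)
        self.diseases = tuple(self.diseases)
        if any(k <= 0 for k in self.lookbacks):
            raise ValueError("lookbacks must be positive")
        unknown = set(self.diseases) - set(inc.CODESETS)
        if unknown:
            raise ValueError(f"unknown disease(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["lookbacks"] = list(self.lookbacks)
        data["diseases"] = list(self.diseases)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def config_hash(self) -> str:
        data = asdict(self)
        data["lookbacks"] = list(self.lookbacks)
        data["diseases"] = list(self.diseases)
        blob = yaml.safe_dump(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_failed(self) -> None:
        if self.errors:
            listing = "\n".join(f"  - {e}" for e in self.errors)
            raise ValueError(f"input validation failed:\n{listing}")


def _check_icd_column(
    df: pd.DataFrame, column: str, table: str, report: ValidationReport,
    allow_multi: bool = False,
) -> None:
    for row, raw in df[column].items():
        if pd.isna(raw) or str(raw).strip() == "":
            if allow_multi:
                continue
            report.errors.append(f"{table} row {row}: empty {column}")
            continue
        codes = str(raw).split(";") if allow_multi else [str(raw)]
        for code in codes:
            code = code.strip()
            if not code:
                continue
            norm = code.upper()
            if not inc._ICD_RE.match(norm):
                report.errors.append(
                    f"{table} row {row}, column {column}: malformed ICD-10 "
                    f"code {code!r}"
                )
            elif norm != code:
                report.warnings.append(
                    f"{table} row {row}, column {column}: code {code!r} "
                    f"normalized to {norm!r}"
                )


def validate_inputs(
    persons: pd.DataFrame,
    spells: pd.DataFrame,
    cases: pd.DataFrame,
) -> ValidationReport:
    """Schema and referential-integrity checks over the three input tables.

    Errors (broken references, reversed dates, malformed codes, out-of-domain
    categories) make the run unusable; warnings (case-normalizable codes)
    do not.
    """
    report = ValidationReport()

    if persons["person_id"].duplicated().any():
        dup = persons.loc[persons["person_id"].duplicated(), "person_id"].iloc[0]
        report.errors.append(f"persons: duplicated person_id {dup!r}")
    bad_sex = persons.loc[~persons["sex"].isin(_SEXES), "sex"]
    if len(bad_sex):
        report.errors.append(
            f"persons row {bad_sex.index[0]}: sex {bad_sex.iloc[0]!r} not in "
            f"{sorted(_SEXES)}"
        )
    if "qualification" in persons.columns:
        bad_q = persons.loc[~persons["qualification"].isin(_QUALS), "qualification"]
        if len(bad_q):
            report.errors.append(
                f"persons row {bad_q.index[0]}: qualification {bad_q.iloc[0]!r} "
                "out of domain"
            )
    if "income_group" in persons.columns:
        bad_i = persons.loc[~persons["income_group"].isin(_INCOMES), "income_group"]
        if len(bad_i):
            report.errors.append(
                f"persons row {bad_i.index[0]}: income_group {bad_i.iloc[0]!r} "
                "out of domain"
            )
    if "income_value" in persons.columns:
        vals = pd.to_numeric(persons["income_value"], errors="coerce")
        neg = vals.dropna() < 0
        if neg.any():
            row = neg[neg].index[0]
            report.errors.append(
                f"persons row {row}: negative income_value "
                f"{persons.loc[row, 'income_value']!r}"
            )

    known = set(persons["person_id"])
    start = pd.to_datetime(spells["start_date"], errors="coerce")
    end = pd.to_datetime(spells["end_date"], errors="coerce")
    unparsed = spells.index[start.isna() | end.isna()]
    for row in unparsed[:5]:
        report.errors.append(f"spells row {row}: unparseable date")
    reversed_rows = spells.index[(end < start).fillna(False)]
    for row in reversed_rows[:5]:
        report.errors.append(
            f"spells row {row}: end_date {spells.loc[row, 'end_date']} before "
            f"start_date {spells.loc[row, 'start_date']}"
        )
    if len(reversed_rows) > 5:
        report.errors.append(
            f"spells: {len(reversed_rows) - 5} further reversed spell(s)"
        )
    orphan_spells = spells.loc[~spells["person_id"].isin(known), "person_id"]
    if len(orphan_spells):
        report.errors.append(
            f"spells row {orphan_spells.index[0]}: unknown person_id "
            f"{orphan_spells.iloc[0]!r} ({len(orphan_spells)} orphan spell rows)"
        )

    adm = pd.to_datetime(cases["admission_date"], errors="coerce")
    for row in cases.index[adm.isna()][:5]:
        report.errors.append(f"cases row {row}: unparseable admission_date")
    orphan_cases = cases.loc[~cases["person_id"].isin(known), "person_id"]
    if len(orphan_cases):
        report.errors.append(
            f"cases row {orphan_cases.index[0]}: unknown person_id "
            f"{orphan_cases.iloc[0]!r} ({len(orphan_cases)} orphan case rows)"
        )
    _check_icd_column(cases, "main_dx", "cases", report)
    if "secondary_dx" in cases.columns:
        _check_icd_column(cases, "secondary_dx", "cases", report, allow_multi=True)
    return report


def read_tables(config: RunConfig):
    """Load persons, spells and cases CSVs with parsed dates."""
    persons = pd.read_csv(config.persons_path)
    spells = pd.read_csv(config.spells_path,
                         parse_dates=["start_date", "end_date"])
    cases = pd.read_csv(config.cases_path, parse_dates=["admission_date"])
    if "secondary_dx" in cases.columns:
        cases["secondary_dx"] = cases["secondary_dx"].fillna("")
    return persons, spells, cases


def _normalize_case_codes(cases: pd.DataFrame) -> pd.DataFrame:
    cases = cases.copy()
    cases["main_dx"] = cases["main_dx"].astype(str).str.strip().str.upper()
    if "secondary_dx" in cases.columns:
        cases["secondary_dx"] = (
            cases["secondary_dx"].fillna("").astype(str).str.strip().str.upper()
        )
    return cases


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle to ``out_dir``.

    Writes ``cohort_sizes.csv``, ``selectivity_<stratifier>.csv`` (one per
    stratifier, all lookbacks stacked), ``age_summary.csv``,
    ``rates_crude.csv``, ``rates_standardized.csv``, ``gradient.csv`` and
    ``run_log.txt`` (row counts per stage and the config hash).  On failure
    any partially written outputs are removed.

    Returns the in-memory bundle (DataFrames keyed like the files).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = [f"config_hash: {config.config_hash()}"]

    def _write(name: str, df: pd.DataFrame) -> None:
        path = out_dir / name
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)
        log_lines.append(f"wrote {name}: {len(df)} rows")

    try:
        persons, spells, cases = read_tables(config)
        log_lines.append(
            f"inputs: {len(persons)} persons, {len(spells)} spells, "
            f"{len(cases)} cases"
        )
        report = validate_inputs(persons, spells, cases)
        for w in report.warnings:
            logger.warning("validation: %s", w)
        report.raise_if_failed()
        cases = _normalize_case_codes(cases)

        classification = IncomeClassification(
            config.income_low_bound, config.income_high_bound
        )
        if "income_group" not in persons.columns:
            persons = persons.copy()
            persons["income_group"] = classify_income_values(
                persons.get("income_value", pd.Series(index=persons.index)),
                classification,
            )

        assignments = build_cohorts(
            persons, spells, config.index_year, config.lookbacks,
            min_age=config.min_age,
            gap_tolerance_days=config.gap_tolerance_days,
        )
        sizes = reduction_table(assignments)
        log_lines.append(
            "cohorts: "
            + ", ".join(f"{r.subpopulation}={r.n}" for r in sizes.itertuples())
        )
        _write("cohort_sizes.csv", sizes)

        for stratifier, bins in (
            ("age_bin", FIVE_YEAR_BINS),
            ("qualification", None),
            ("income_group", None),
        ):
            tables = [
                exclusion_by_stratum(
                    assignments, persons, stratifier, k,
                    index_year=config.index_year, by_sex=True,
                    age_bins=bins or FIVE_YEAR_BINS,
                )
                for k in sorted(config.lookbacks)
            ]
            _write(f"selectivity_{stratifier}.csv", pd.concat(tables,
                                                              ignore_index=True))

        # age summaries per subpopulation and sex
        summary_rows = []
        for label, mask in [("BASE", assignments["in_base"])] + [
            (f"CON{k}", assignments[f"in_con_{k}"]) for k in sorted(config.lookbacks)
        ]:
            members = persons[persons["person_id"].isin(assignments.index[mask])]
            for sex, sub in members.groupby("sex"):
                med, q1, q3 = age_summary(sub, config.index_year)
                summary_rows.append(
                    {"subpopulation": label, "sex": sex, "median_age": med,
                     "q1_age": q1, "q3_age": q3}
                )
        _write("age_summary.csv", pd.DataFrame(summary_rows))

        crude_all, std_all, grad_all = [], [], []
        results = {}
        for disease in config.diseases:
            result = inc.rate_analysis(
                persons, spells, cases, assignments,
                inc.CODESETS[disease], config.index_year,
                lookbacks=config.lookbacks,
                censor_at_event=config.censor_at_event,
                use_secondary_history=config.use_secondary_history,
                full_history=config.i252_full_history,
                gap_tolerance_days=config.gap_tolerance_days,
            )
            results[disease] = result
            for key, acc in (("crude", crude_all), ("standardized", std_all),
                             ("gradient", grad_all)):
                df = result[key].copy()
                df.insert(0, "disease", disease)
                acc.append(df)
        crude = pd.concat(crude_all, ignore_index=True)
        standardized = pd.concat(std_all, ignore_index=True)
        gradient = pd.concat(grad_all, ignore_index=True)
        _write("rates_crude.csv", crude)
        _write("rates_standardized.csv", standardized)
        _write("gradient.csv", gradient)

        if config.make_plots:
            from . import plots

            for disease in config.diseases:
                fig = plots.plot_crude_rates(
                    crude[crude["disease"] == disease], disease
                )
                path = out_dir / f"crude_rates_{disease}.svg"
                plots.save_deterministic(fig, path)
                written.append(path)
            sel = pd.read_csv(out_dir / "selectivity_age_bin.csv")
            fig = plots.plot_exclusion_by_age(sel)
            path = out_dir / "exclusion_by_age.svg"
            plots.save_deterministic(fig, path)
            written.append(path)

        (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        written.append(out_dir / "run_log.txt")
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise

    return {
        "cohort_sizes": sizes,
        "assignments": assignments,
        "crude": crude,
        "standardized": standardized,
        "gradient": gradient,
        "results": results,
        "log": log_lines,
    }
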