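"""End-to-end latent-class analysis driver.

Mirrors the analysis sequence of the study: fit mixtures with an increasing
number of latent classes, judge each by the mean- and covariance-structure
statistics, select the smallest class count whose covariance-structure
p-value clears the configured alpha, probe which parameters actually differ
across classes with equality-restriction likelihood-ratio tests, assign each
subject to the class with the highest posterior probability, and cross-
tabulate the assignment against the manifest group label.

The report is a plain JSON-serialisable dictionary; identical inputs and seed
give a byte-identical report apart from the recorded runtime.
"""

from __future__ import annotations

import json
import time

import numpy as np

from . import __version__
from .contingency import association_tests
from .estimation import Restriction, assign_classes, em_fit, lr_test
from .fitstats import m3_statistic, s1_statistic
from .io import read_dataset
from .model import Dataset
from .simulate import SimConfig, simulate

__all__ = ["run_pipeline", "report_json", "validate_report", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1.0"

#: key -> (required, type) for the top level of a pipeline report.
_REPORT_SCHEMA: dict[str, tuple[bool, type]] = {
    "schema_version": (True, str),
    "fits": (True, dict),
    "selected_K": (True, int),
    "selection": (True, dict),
    "restriction_tests": (True, dict),
    "assignment": (True, dict),
    "group_association": (False, dict),
    "subject_table": (True, list),
    "meta": (True, dict),
}


def _stat_entry(stat) -> dict:
    return {
        "value": None if not np.isfinite(stat.value) else float(stat.value),
        "df": stat.df,
        "p_value": stat.p_value,
        "warnings": list(stat.warnings),
    }


def _fit_entry(fit, m3, s1) -> dict:
    return {
        "loglik": float(fit.loglik),
        "converged": bool(fit.converged),
        "n_iterations": int(fit.n_iterations),
        "n_free_params": int(fit.n_free_params),
        "weights": [float(w) for w in fit.model.weights],
        "params": [{"b": p.b, "g": p.g, "s": p.s} for p in fit.model.params],
        "M3": _stat_entry(m3),
        "S1": _stat_entry(s1),
    }


def run_pipeline(
    data: Dataset | SimConfig | str,
    max_K: int = 3,
    alpha_fit: float = 0.01,
    n_starts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 2000,
    seed: int = 0,
) -> dict:
    """Run the full latent-class analysis and return the report dictionary.

    ``data`` may be a Dataset, a path to a cohort CSV, or a SimConfig (which
    is simulated first; its own seed controls the draw).  The class count is
    chosen as the smallest K whose covariance-structure p-value exceeds
    ``alpha_fit``; if no testable K qualifies, the largest K is kept and the
    report says so.  Equality-restriction tests for b, g and s are run at the
    selected K when it is at least 2.
    """
    t0 = time.perf_counter()
    if isinstance(data, SimConfig):
        dataset = simulate(data).dataset
    elif isinstance(data, Dataset):
        dataset = data
    else:
        dataset = read_dataset(data)

    ss = np.random.SeedSequence(seed)
    fit_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4 * max_K)]

    fits: dict[int, object] = {}
    fit_table: dict[str, dict] = {}
    s1_by_K: dict[int, object] = {}
    for K in range(1, max_K + 1):
        try:
            fit = em_fit(dataset, K, n_starts=n_starts, tol=tol, max_iter=max_iter, seed=fit_seeds[K - 1])
        except ValueError as exc:
            raise ValueError(f"[fit K={K}] {exc}") from exc
        m3 = m3_statistic(dataset, fit)
        s1 = s1_statistic(dataset, fit)
        fits[K] = fit
        s1_by_K[K] = s1
        fit_table[str(K)] = _fit_entry(fit, m3, s1)

    selected = None
    for K in range(1, max_K + 1):
        s1 = s1_by_K[K]
        if s1.p_value is not None and s1.p_value > alpha_fit:
            selected = K
            break
    rule_satisfied = selected is not None
    if selected is None:
        # fall back to the largest fitted model; flagged in the report
        selected = max_K

    restriction_tests: dict[str, dict] = {}
    if selected >= 2:
        full = fits[selected]
        for i, name in enumerate(("b", "g", "s")):
            try:
                restricted = em_fit(
                    dataset,
                    selected,
                    n_starts=n_starts,
                    tol=tol,
                    max_iter=max_iter,
                    seed=fit_seeds[max_K + i],
                    restriction=Restriction(name),
                )
                test = lr_test(full, restricted)
            except ValueError as exc:
                raise ValueError(f"[restriction {name}] {exc}") from exc
            restriction_tests[name] = {
                "delta_l": float(test.delta_l),
                "df": int(test.df),
                "p_value": float(test.p_value),
                "restricted_loglik": float(restricted.loglik),
            }

    labels = assign_classes(fits[selected])
    class_sizes = np.bincount(labels, minlength=selected)
    assignment = {
        "labels": [int(v) for v in labels],
        "class_sizes": [int(v) for v in class_sizes],
    }

    group_association = None
    group_levels = None
    if dataset.group is not None:
        group_levels = sorted(set(str(g) for g in dataset.group))
        if selected == 2 and len(group_levels) == 2:
            table = np.zeros((2, 2), dtype=np.int64)
            for gi, g in enumerate(group_levels):
                mask = np.asarray([str(v) == g for v in dataset.group])
                for k in range(2):
                    table[gi, k] = int(np.sum(mask & (labels == k)))
            try:
                result = association_tests(table)
                group_association = {
                    "rows": group_levels,
                    "columns": ["class_0", "class_1"],
                    "table": [list(r) for r in result.table],
                    "chi2": result.chi2,
                    "df": result.df,
                    "p_value": result.p_value,
                    "fisher_p_two_tailed": result.fisher_p_two_tailed,
                }
            except ValueError as exc:
                group_association = {"error": f"[association] {exc}"}

    # tidy per-subject table so any standard ANOVA tool can pick it up
    ids = dataset.subject_ids if dataset.subject_ids is not None else np.arange(1, dataset.N + 1)
    subject_table = []
    for i in range(dataset.N):
        row = {
            "subject_id": int(ids[i]) if np.issubdtype(np.asarray(ids).dtype, np.integer) else str(ids[i]),
            "assigned_class": int(labels[i]),
            "max_posterior": float(fits[selected].posteriors[i].max()),
        }
        if dataset.group is not None:
            row["group"] = str(dataset.group[i])
        for name, values in dataset.covariates.items():
            row[name] = float(values[i])
        subject_table.append(row)

    report = {
        "schema_version": SCHEMA_VERSION,
        "fits": fit_table,
        "selected_K": int(selected),
        "selection": {
            "rule": "smallest K with covariance-structure (S1) p-value > alpha",
            "alpha": float(alpha_fit),
            "satisfied": bool(rule_satisfied),
        },
        "restriction_tests": restriction_tests,
        "assignment": assignment,
        "group_association": group_association,
        "subject_table": subject_table,
        "meta": {
            "package_version": __version__,
            "seed": int(seed),
            "n_starts": int(n_starts),
            "max_K": int(max_K),
            "N": int(dataset.N),
            "T": int(dataset.T),
            "runtime_s": round(time.perf_counter() - t0, 3),
        },
    }
    validate_report(report)
    return report


def report_json(report: dict, include_runtime: bool = True) -> str:
    """Serialise a report deterministically (sorted keys, 2-space indent)."""
    if not include_runtime:
        report = json.loads(json.dumps(report))
        report.get("meta", {}).pop("runtime_s", None)
    return json.dumps(report, indent=2, sort_keys=True)


def validate_report(report: dict) -> None:
    """Check the report against the published schema; raise ValueError if bad."""
    if not isinstance(report, dict):
        raise ValueError("report must be a dictionary")
    for key, (required, typ) in _REPORT_SCHEMA.items():
        if key not in report or report[key] is None:
            if required:
                raise ValueError(f"report is missing required key {key!r}")
            continue
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} must be of type {typ.__name__}")
    unknown = set(report) - set(_REPORT_SCHEMA)
    if unknown:
        raise ValueError(f"report has unknown keys {sorted(unknown)}")
    if str(report["selected_K"]) not in report["fits"]:
        raise ValueError("selected_K has no corresponding fit entry")
    json.dumps(report)  # must be JSON-serialisable
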