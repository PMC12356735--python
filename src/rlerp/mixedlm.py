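"""Design coding, linear mixed models, simple slopes, and influence screening.

The five analysis models regress block accuracy, single-trial choice
switching, and single-trial FRN/P3a/P3b amplitudes on simple-coded factors
(group, feedback timing, feedback valence, learnability, response type at
+-0.5), standardized block, and the centered unsigned prediction error,
with participants as random factors.  Models are fitted with lme4/lmerTest
through an Rscript bridge, so fixed-effect tests use genuine Satterthwaite
degrees of freedom and simple slopes are tested as single-df contrasts
(lmerTest::contest1D).

Random-effect structures are reduced stepwise on convergence failure or
singular fit: random interaction terms are deleted before random main
effects, higher order first, last-listed first within an order.  The fixed
part is never altered.  Cook's distances flag influential observations at
the conventional 4/n cutoff.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CODING",
    "MODEL_TEMPLATES",
    "MLMSpec",
    "MLMResult",
    "code_predictors",
    "reduction_sequence",
    "fit_mlm",
    "fit_mlm_batch",
    "probe_simple_slopes",
    "screen_influence",
]

# simple coding: every categorical predictor at +-0.5
CODING: dict[str, dict[str, float]] = {
    "group": {"patient": 0.5, "control": -0.5},
    "timing": {"delayed": 0.5, "immediate": -0.5},
    "valence": {"positive": 0.5, "negative": -0.5},
    "learnability": {"learnable": 0.5, "unlearnable": -0.5},
    "response_type": {"correct": 0.5, "false": -0.5},
}

# column in the joined events table feeding each coded predictor
_SOURCE_COLUMNS = {
    "group": "group",
    "timing": "session",
    "valence": "feedback_valence",
    "learnability": "learnability",
    "response_type": "response_type",
}


@dataclass(frozen=True)
class MLMSpec:
    """One mixed-model specification: fixed formula right-hand side, the
    maximal per-participant random-slope terms (intercept implicit), and the
    model family."""

    response: str
    fixed: str
    random_terms: tuple[str, ...] = ()
    family: str = "gaussian"  # switch models may opt into "binomial"
    reml: bool = True
    group_var: str = "participant"

    @property
    def formula(self) -> str:
        re = " + ".join(("1",) + self.random_terms)
        return f"{self.response} ~ {self.fixed} + ({re} | {self.group_var})"

    def variables(self) -> list[str]:
        seen: dict[str, None] = {}
        for token in (
            self.fixed.replace("*", " ").replace(":", " ").replace("+", " ").split()
        ):
            if token != "1":
                seen.setdefault(token)
        return list(seen)


MODEL_TEMPLATES: dict[str, MLMSpec] = {
    "accuracy": MLMSpec(
        response="accuracy",
        fixed="group*timing*block_scaled",
        random_terms=("timing", "block_scaled", "timing:block_scaled"),
    ),
    "switching": MLMSpec(
        response="switch",
        fixed="group*timing*valence*response_type*block_scaled",
        random_terms=("timing", "valence", "response_type", "valence:response_type"),
    ),
    "frn": MLMSpec(
        response="frn",
        fixed="group*timing*upe*valence*learnability",
        random_terms=(
            "timing",
            "valence",
            "timing:valence",
            "learnability",
            "valence:learnability",
            "timing:learnability",
        ),
    ),
    "p3a": MLMSpec(
        response="p3a",
        fixed="group*timing*upe*valence*learnability",
        random_terms=("timing", "valence"),
    ),
    "p3b": MLMSpec(
        response="p3b",
        fixed="group*timing*upe*valence*learnability",
        random_terms=("timing", "valence", "upe", "timing:upe"),
    ),
}


def code_predictors(
    table: pd.DataFrame,
    carry: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Apply simple coding to a joined events/PE/ERP table.

    Recognized source columns are mapped to numeric +-0.5 predictors
    (``group``, ``timing``, ``valence``, ``learnability``,
    ``response_type``); ``block`` is standardized over the supplied rows to
    ``block_scaled``; ``upe`` and any response/carry columns pass through.
    Unknown factor levels raise a ValueError.
    """
    out = pd.DataFrame(index=table.index)
    out["participant"] = table["participant"]
    for coded, source in _SOURCE_COLUMNS.items():
        if source not in table.columns:
            continue
        mapping = CODING[coded]
        vals = table[source]
        known = vals.isin(mapping) | vals.isna()
        if not known.all():
            bad = sorted(set(vals[~known].astype(str)))
            raise ValueError(f"unknown level(s) for {coded}: {bad}")
        out[coded] = vals.map(mapping)
    if "block" in table.columns:
        b = table["block"].astype(float)
        out["block_scaled"] = (b - b.mean()) / b.std(ddof=1)
    if "upe" in table.columns:
        out["upe"] = table["upe"].astype(float)
    for col in carry:
        out[col] = table[col]
    return out


def _term_order(term: str) -> int:
    return term.count(":") + 1


def reduction_sequence(random_terms: tuple[str, ...]) -> list[list[str]]:
    """Ordered random structures to try: the maximal structure, then one
    term deleted at a time (highest interaction order first, last-listed
    first within an order) down to intercept-only."""
    terms = list(random_terms)
    seq = [list(terms)]
    while terms:
        order = max(_term_order(t) for t in terms)
        # last-listed among the highest-order terms
        victim = max(i for i, t in enumerate(terms) if _term_order(t) == order)
        terms = terms[:victim] + terms[victim + 1 :]
        seq.append(list(terms))
    return seq


@dataclass
class MLMResult:
    """Fitted mixed model: fixed-effect table (estimate, se, Satterthwaite
    df, t, p), coefficient covariance, the realized random structure, and
    per-observation diagnostics."""

    spec: MLMSpec
    coefficients: pd.DataFrame
    vcov: pd.DataFrame | None
    random_terms: tuple[str, ...]
    singular: bool
    converged: bool
    sigma: float
    nobs: int
    residuals: np.ndarray | None = None
    fitted: np.ndarray | None = None
    hatvalues: np.ndarray | None = None
    group_ids: np.ndarray | None = None
    messages: list[str] = field(default_factory=list)
    design: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def coef_names(self) -> list[str]:
        return list(self.coefficients.index)

    def to_tables(self, tsv_path, json_path) -> None:
        """Write the coefficient table (TSV) and fit metadata (JSON)."""
        self.coefficients.to_csv(tsv_path, sep="\t", na_rep="n/a")
        meta = {
            "formula": self.spec.formula,
            "realized_random_terms": list(self.random_terms),
            "singular": self.singular,
            "converged": self.converged,
            "nobs": self.nobs,
            "sigma": self.sigma,
        }
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=1)


class MLMConvergenceError(RuntimeError):
    pass


def _rscript_path() -> str:
    exe = shutil.which("Rscript")
    if exe is None:
        raise RuntimeError("Rscript not found on PATH; the mixed-model backend needs R")
    return exe


def _run_r(workdir: Path) -> dict:
    script = resources.files("rlerp").joinpath("_lmer.R")
    with resources.as_file(script) as script_path:
        proc = subprocess.run(
            [_rscript_path(), "--vanilla", str(script_path), str(workdir)],
            capture_output=True,
            text=True,
        )
    result_path = workdir / "result.json"
    if proc.returncode != 0 or not result_path.exists():
        raise RuntimeError(
            f"R mixed-model backend failed (exit {proc.returncode}):\n{proc.stderr[-4000:]}"
        )
    with open(result_path) as fh:
        return json.load(fh)


def _model_columns(design: pd.DataFrame, spec: MLMSpec, extra: tuple[str, ...] = ()) -> pd.DataFrame:
    cols = [spec.group_var, spec.response] + spec.variables() + list(extra)
    missing = [c for c in cols if c not in design.columns]
    if missing:
        raise ValueError(f"design table lacks columns: {missing}")
    sub = design[cols].dropna(subset=[spec.response] + spec.variables())
    return sub


def _aslist(x) -> list:
    """jsonlite auto-unboxes length-1 vectors; normalize back to lists."""
    return x if isinstance(x, list) else [x]


def _coef_frame(raw: dict) -> pd.DataFrame:
    tab = pd.DataFrame({k: _aslist(v) for k, v in raw.items()})
    if "_row" in tab.columns:  # jsonlite serializes data.frame rownames
        tab = tab.drop(columns="_row")
    tab = tab.set_index("name")
    tab["df"] = tab["df"].astype(float)
    return tab


def fit_mlm(
    design: pd.DataFrame,
    spec: MLMSpec,
    structures: list[list[str]] | None = None,
    _contrasts: dict | None = None,
    _influence_groups: bool = False,
) -> MLMResult:
    """Fit one mixed model with stepwise random-structure reduction.

    Attempts the maximal random structure from ``spec`` and deletes random
    terms (interaction terms first, higher order first, last-listed first)
    whenever the fit fails to converge or is singular; the intercept-only
    structure is accepted even when singular.  Raises MLMConvergenceError
    when no structure converges, naming the last attempted structure.
    """
    if design[spec.group_var].nunique() < 2:
        raise ValueError("need at least two participants")
    data = _model_columns(design, spec)
    if data[spec.response].nunique() < 2:
        raise ValueError("response is degenerate (fewer than two distinct values)")
    payload = {
        "response": spec.response,
        "fixed": spec.fixed,
        "random_structures": structures
        if structures is not None
        else reduction_sequence(spec.random_terms),
        "group_var": spec.group_var,
        "reml": spec.reml,
        "family": spec.family,
    }
    if _contrasts is not None:
        payload["contrasts"] = _contrasts
    if _influence_groups:
        payload["influence_groups"] = True
    with tempfile.TemporaryDirectory(prefix="rlerp_lmer_") as tmp:
        workdir = Path(tmp)
        data.to_csv(workdir / "data.tsv", sep="\t", index=False, na_rep="NA")
        with open(workdir / "spec.json", "w") as fh:
            json.dump(payload, fh)
        raw = _run_r(workdir)
    if not raw.get("converged", False):
        attempted = raw.get("log", [])
        last = attempted[-1]["random_terms"] if attempted else []
        raise MLMConvergenceError(
            f"no random structure converged; last attempted: (1 + {' + '.join(last) or '1'} "
            f"| {spec.group_var})"
        )
    coefs = _coef_frame(raw["coefficients"])
    vcov = None
    if "vcov" in raw:
        names = _aslist(raw.get("coef_names", list(coefs.index)))
        vcov = pd.DataFrame(
            np.atleast_2d(np.asarray(raw["vcov"], dtype=float)), index=names, columns=names
        )
    result = MLMResult(
        spec=spec,
        coefficients=coefs,
        vcov=vcov,
        random_terms=tuple(raw.get("random_terms", [])),
        singular=bool(raw.get("singular", False)),
        converged=True,
        sigma=float(raw["sigma"]),
        nobs=int(raw["nobs"]),
        residuals=np.asarray(_aslist(raw["residuals"]), dtype=float) if "residuals" in raw else None,
        fitted=np.asarray(raw["fitted"], dtype=float) if "fitted" in raw else None,
        hatvalues=np.asarray(_aslist(raw["hatvalues"]), dtype=float) if "hatvalues" in raw else None,
        group_ids=np.asarray(raw["group_ids"]) if "group_ids" in raw else None,
        messages=[str(m) for m in raw.get("messages", [])],
        design=design,
    )
    if "contrast_results" in raw:
        result.contrast_results = raw["contrast_results"]  # type: ignore[attr-defined]
    if "group_cooks" in raw:
        result.group_cooks = pd.Series(  # type: ignore[attr-defined]
            np.asarray(_aslist(raw["group_cooks"]), dtype=float),
            index=_aslist(raw["group_levels"])
        )
    return result


def fit_mlm_batch(
    design: pd.DataFrame, spec: MLMSpec, rep_col: str = "rep"
) -> pd.DataFrame:
    """Fit the same model independently for every replicate in one R
    session (used for Monte-Carlo calibration).  Returns a long coefficient
    table with columns rep, name, estimate, se, df, t, p, singular,
    random_terms; replicates that fail to converge are omitted."""
    payload = {
        "response": spec.response,
        "fixed": spec.fixed,
        "random_structures": reduction_sequence(spec.random_terms),
        "group_var": spec.group_var,
        "reml": spec.reml,
        "family": spec.family,
        "batch_col": rep_col,
        "skip_diagnostics": True,
    }
    data = _model_columns(design, spec, extra=(rep_col,))
    with tempfile.TemporaryDirectory(prefix="rlerp_lmer_") as tmp:
        workdir = Path(tmp)
        data.to_csv(workdir / "data.tsv", sep="\t", index=False, na_rep="NA")
        with open(workdir / "spec.json", "w") as fh:
            json.dump(payload, fh)
        raw = _run_r(workdir)
    frames = []
    for fit in raw["fits"]:
        if not fit.get("converged", False):
            continue
        tab = _coef_frame(fit["coefficients"]).reset_index()
        tab[rep_col] = fit["rep"]
        tab["singular"] = bool(fit.get("singular", False))
        tab["random_terms"] = " + ".join(fit.get("random_terms", []))
        frames.append(tab)
    if not frames:
        raise MLMConvergenceError("no replicate converged")
    return pd.concat(frames, ignore_index=True)


def _contrast_vector(
    coef_names: list[str], focal: str, at: dict[str, float]
) -> np.ndarray:
    """Weights of d(linear predictor)/d(focal) at the given moderator
    levels, with all other centered covariates at 0."""
    moderators = set(at)
    c = np.zeros(len(coef_names))
    for i, name in enumerate(coef_names):
        if name == "(Intercept)":
            continue
        parts = name.split(":")
        if focal not in parts:
            continue
        others = [p for p in parts if p != focal]
        if len(others) != len(parts) - 1:  # focal appears twice; not expected
            continue
        if all(o in moderators for o in others):
            c[i] = float(np.prod([at[o] for o in others])) if others else 1.0
    return c


def probe_simple_slopes(
    result: MLMResult, focal: str, moderators: list[str]
) -> pd.DataFrame:
    """Simple slopes of ``focal`` at every crossing of the moderator levels.

    Each slope is the corresponding linear combination of fixed-effect
    coefficients; its SE/df/t/p come from a single-df Satterthwaite contrast
    on a refit of the realized model.  Moderator levels are the two coded
    levels (+-0.5) with their factor labels.
    """
    names = result.coef_names
    if focal not in result.spec.variables():
        raise ValueError(f"focal predictor {focal!r} not in the model")
    for m in moderators:
        if m not in result.spec.variables():
            raise ValueError(f"moderator {m!r} not in the fitted model")
        if not any(
            focal in n.split(":") and m in n.split(":") for n in names
        ):
            raise ValueError(f"no {focal} x {m} interaction among fixed effects")
    if result.design is None:
        raise ValueError("result lacks the design table; refit with fit_mlm")

    level_sets = []
    for m in moderators:
        labels = CODING.get(m)
        if labels:
            level_sets.append([(lab, val) for lab, val in labels.items()])
        else:
            level_sets.append([("+0.5", 0.5), ("-0.5", -0.5)])
    combos = list(product(*level_sets))
    labels = []
    matrix = []
    for combo in combos:
        at = {m: val for m, (_, val) in zip(moderators, combo)}
        matrix.append(_contrast_vector(names, focal, at).tolist())
        labels.append("|".join(lab for lab, _ in combo))

    refit = fit_mlm(
        result.design,
        result.spec,
        structures=[list(result.random_terms)],
        _contrasts={"labels": labels, "matrix": matrix, "coef_names": names},
    )
    rows = []
    for combo, res in zip(combos, getattr(refit, "contrast_results")):
        row = {m: lab for m, (lab, _) in zip(moderators, combo)}
        row.update(
            estimate=res["estimate"],
            se=res["se"],
            df=res["df"],
            t=res["t"],
            p=res["p"],
        )
        rows.append(row)
    return pd.DataFrame(rows)


def screen_influence(
    result: MLMResult, threshold: float | None = None, level: str = "observation"
) -> pd.DataFrame:
    """Cook's distances above the 4/n cutoff (default) are flagged;
    removal is the caller's choice.

    ``level="observation"`` uses the standard leverage form
    D_i = r_i^2 h_i / (p * sigma^2 * (1 - h_i)^2) with the mixed-model hat
    values and conditional residuals (identical to lme4's
    ``cooks.distance``); n is the number of observations.
    ``level="participant"`` computes exact delete-one-participant Cook's
    distances by refitting without each participant (n = number of
    participants) — a participant-level shift is otherwise absorbed by that
    participant's random intercept and invisible to conditional residuals.
    """
    if level == "participant":
        if result.design is None:
            raise ValueError("result lacks the design table; refit with fit_mlm")
        refit = fit_mlm(
            result.design,
            result.spec,
            structures=[list(result.random_terms)],
            _influence_groups=True,
        )
        d = getattr(refit, "group_cooks")
        if threshold is None:
            threshold = 4.0 / len(d)
        return pd.DataFrame(
            {"participant": d.index, "cooks_distance": d.to_numpy(), "flagged": d.to_numpy() > threshold}
        )
    if level != "observation":
        raise ValueError("level must be 'observation' or 'participant'")
    if result.residuals is None or result.hatvalues is None:
        raise ValueError("result lacks residuals/hatvalues diagnostics")
    e = result.residuals
    h = np.clip(result.hatvalues, 0.0, 1.0 - 1e-12)
    p = len(result.coef_names)
    d = (e**2 * h) / (p * result.sigma**2 * (1.0 - h) ** 2)
    if threshold is None:
        threshold = 4.0 / result.nobs
    out = pd.DataFrame(
        {
            "cooks_distance": d,
            "flagged": d > threshold,
        }
    )
    if result.group_ids is not None:
        out.insert(0, "participant", result.group_ids)
    return out
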