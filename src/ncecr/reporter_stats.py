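"""Dual-luciferase reporter analysis.

Each well yields a firefly/Renilla luminescence ratio (the Renilla
channel is the transfection control measured in the same sample).
Ratios are normalized to the promoter-only control construct ("prom"),
per experiment when experiment identifiers are present. Per element the
fold change versus the control is estimated (arithmetic mean of
normalized ratios; the median is reported alongside) and compared with
the control wells by a two-sample Student's t-test (pooled variance by
default, Welch behind a flag). Elements with p < alpha are classified
enhancer (fold > 1) or silencer (fold < 1); everything else is neutral.
No multiple-testing correction is applied by default; Benjamini-
Hochberg is available behind a flag.
"""

from __future__ import annotations

import math
import os
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05
DEFAULT_CONTROL = "prom"


@dataclass(frozen=True)
class LuciferaseWell:
    """One well of a dual-luciferase plate.

    Either raw two-channel luminescence (``firefly`` and ``renilla``,
    both positive) or a pre-computed ``ratio`` (for ratio-level tables)
    must be present.
    """

    construct: str
    experiment: str | None = None
    replicate: str | None = None
    firefly: float | None = None
    renilla: float | None = None
    ratio: float | None = None

    def __post_init__(self) -> None:
        if self.ratio is None and (self.firefly is None or self.renilla is None):
            raise ValueError(
                f"well for {self.construct!r}: need firefly+renilla or a ratio"
            )
        for name in ("firefly", "renilla", "ratio"):
            v = getattr(self, name)
            if v is not None and not (v > 0 and math.isfinite(v)):
                raise ValueError(f"well for {self.construct!r}: {name} must be positive, got {v}")

    @property
    def value(self) -> float:
        """The firefly/Renilla ratio of this well."""
        if self.ratio is not None:
            return self.ratio
        return self.firefly / self.renilla


@dataclass(frozen=True)
class ElementResult:
    """Per-construct reporter outcome versus the promoter-only control."""

    construct: str
    n: int
    fold: float            # arithmetic mean of normalized ratios
    fold_median: float
    t: float
    p: float
    element_class: str     # enhancer | silencer | neutral


_SERIES_RE = re.compile(r"(U|In|I|D)\s*[-_]?(\d+)(?:[-._](\d+))?", re.IGNORECASE)
_SERIES_RANK = {"U": 0, "IN": 1, "I": 1, "D": 2}


def construct_sort_key(construct: str):
    """Sort key following the locus label series U*, In*/I*, D*.

    Non-matching constructs (e.g. 'bas', 'con') sort after the series,
    alphabetically.
    """
    m = _SERIES_RE.fullmatch(construct.strip())
    if m:
        series = _SERIES_RANK[m.group(1).upper()]
        return (0, series, int(m.group(2)), int(m.group(3) or 0), construct)
    return (1, 0, 0, 0, construct)


def normalize_to_control(
    wells: list[LuciferaseWell], control_id: str = DEFAULT_CONTROL
) -> np.ndarray:
    """Per-well ratios normalized to the control construct's mean ratio.

    When experiment ids are present, each well is divided by the mean
    control ratio of its own experiment (falling back to the global
    control mean, with a warning, for experiments lacking control wells);
    otherwise by the global control mean. Control wells normalize to mean
    exactly 1. The returned array is aligned with ``wells``.
    """
    control = [w for w in wells if w.construct == control_id]
    if not control:
        raise ValueError(f"no control wells with construct id {control_id!r}")
    global_mean = float(np.mean([w.value for w in control]))
    per_experiment: dict[str, float] = {}
    use_experiments = all(w.experiment is not None for w in wells)
    if use_experiments:
        by_exp: dict[str, list[float]] = {}
        for w in control:
            by_exp.setdefault(w.experiment, []).append(w.value)
        per_experiment = {e: float(np.mean(v)) for e, v in by_exp.items()}
    out = np.empty(len(wells))
    warned = False
    for i, w in enumerate(wells):
        if use_experiments:
            denom = per_experiment.get(w.experiment)
            if denom is None:
                if not warned:
                    warnings.warn(
                        f"experiment {w.experiment!r} has no {control_id!r} wells; "
                        "using the global control mean",
                        stacklevel=2,
                    )
                    warned = True
                denom = global_mean
        else:
            denom = global_mean
        out[i] = w.value / denom
    return out


def t_test_two_sample(x, y, welch: bool = False) -> tuple[float, float]:
    """Two-sample Student's t-test (pooled variance, two-sided).

    Degenerate zero-variance inputs: p = 1 (t = 0) when the means are
    equal, otherwise p -> 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            return 0.0, 1.0
        warnings.warn("zero variance in both samples with unequal means; p -> 0", stacklevel=2)
        return math.copysign(math.inf, x[0] - y[0]), 0.0
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def _classify(fold: float, p: float, alpha: float) -> str:
    if p < alpha and fold > 1:
        return "enhancer"
    if p < alpha and fold < 1:
        return "silencer"
    return "neutral"


def classify_elements(
    wells: list[LuciferaseWell],
    alpha: float = DEFAULT_ALPHA,
    control_id: str = DEFAULT_CONTROL,
    welch: bool = False,
    fdr: bool = False,
) -> list[ElementResult]:
    """Normalize, test and classify every non-control construct.

    Elements with fewer than 2 wells are skipped with a warning. With
    ``fdr=True``, p-values are Benjamini-Hochberg adjusted before
    classification. Results are sorted by the locus label series
    (U*, In*/I*, D*, then others).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    normalized = normalize_to_control(wells, control_id)
    by_construct: dict[str, list[float]] = {}
    for w, v in zip(wells, normalized):
        by_construct.setdefault(w.construct, []).append(v)
    control_values = np.asarray(by_construct[control_id])
    if control_values.size < 2:
        raise ValueError(f"need >= 2 control wells for {control_id!r}")

    rows = []
    for construct, values in by_construct.items():
        if construct == control_id:
            continue
        if len(values) < 2:
            warnings.warn(
                f"construct {construct!r} has {len(values)} well(s); skipped", stacklevel=2
            )
            continue
        values = np.asarray(values)
        t, p = t_test_two_sample(values, control_values, welch=welch)
        rows.append((construct, values, t, p))

    pvals = np.array([r[3] for r in rows])
    if fdr and pvals.size:
        pvals = _benjamini_hochberg(pvals)

    results = []
    for (construct, values, t, _), p in zip(rows, pvals):
        fold = float(values.mean())
        results.append(
            ElementResult(
                construct, len(values), fold, float(np.median(values)),
                t, float(p), _classify(fold, float(p), alpha),
            )
        )
    results.sort(key=lambda r: construct_sort_key(r.construct))
    return results


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# Table I/O: long raw/ratio format and the wide ratio-level layout used by
# deposited combined datasets (one column group per element, values already
# expressed as firefly/Renilla ratios)
# ---------------------------------------------------------------------------


def read_assay_table(path: str | os.PathLike) -> list[LuciferaseWell]:
    """Read a TSV/CSV assay table, auto-detecting the layout.

    Long raw: columns construct, firefly, renilla (+ optional experiment,
    replicate). Long ratio: construct, ratio. Anything else is treated as
    a wide ratio table: every non-'experiment' column is a construct and
    each cell one well's normalized ratio (blank cells allowed -> ragged
    replicate counts).
    """
    path = os.fspath(path)
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    wells: list[LuciferaseWell] = []
    if "construct" in cols and "firefly" in cols and "renilla" in cols:
        for r in df.itertuples(index=False):
            d = {k.lower(): v for k, v in zip(df.columns, r)}
            wells.append(
                LuciferaseWell(
                    str(d["construct"]),
                    experiment=_opt_str(d.get("experiment")),
                    replicate=_opt_str(d.get("replicate")),
                    firefly=float(d["firefly"]),
                    renilla=float(d["renilla"]),
                )
            )
    elif "construct" in cols and "ratio" in cols:
        for r in df.itertuples(index=False):
            d = {k.lower(): v for k, v in zip(df.columns, r)}
            wells.append(
                LuciferaseWell(
                    str(d["construct"]),
                    experiment=_opt_str(d.get("experiment")),
                    replicate=_opt_str(d.get("replicate")),
                    ratio=float(d["ratio"]),
                )
            )
    else:  # wide ratio layout
        exp_col = cols.get("experiment")
        for idx, row in df.iterrows():
            experiment = _opt_str(row[exp_col]) if exp_col else None
            for col in df.columns:
                if col == exp_col:
                    continue
                v = row[col]
                if pd.isna(v):
                    continue
                wells.append(
                    LuciferaseWell(
                        str(col), experiment=experiment, replicate=str(idx),
                        ratio=float(v),
                    )
                )
    return wells


def _opt_str(v) -> str | None:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return str(v)


def write_wells_tsv(wells: list[LuciferaseWell], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("construct\texperiment\treplicate\tfirefly\trenilla\n")
        for w in wells:
            fh.write(
                f"{w.construct}\t{w.experiment or ''}\t{w.replicate or ''}\t"
                f"{'' if w.firefly is None else f'{w.firefly:.6f}'}\t"
                f"{'' if w.renilla is None else f'{w.renilla:.6f}'}\n"
            )


def write_results_tsv(results: list[ElementResult], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("construct\tn\tfold\tfold_median\tt\tp\tclass\n")
        for r in results:
            fh.write(
                f"{r.construct}\t{r.n}\t{r.fold:.4f}\t{r.fold_median:.4f}\t"
                f"{r.t:.4f}\t{r.p:.3e}\t{r.element_class}\n"
            )


def plot_results(
    wells: list[LuciferaseWell],
    path: str | os.PathLike,
    control_id: str = DEFAULT_CONTROL,
    alpha: float = DEFAULT_ALPHA,
) -> None:
    """Box plots of normalized ratios per construct (enhancers red,
    silencers green, as in the conventional figure layout)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    normalized = normalize_to_control(wells, control_id)
    by_construct: dict[str, list[float]] = {}
    for w, v in zip(wells, normalized):
        by_construct.setdefault(w.construct, []).append(v)
    results = {r.construct: r for r in classify_elements(wells, alpha, control_id)}
    order = sorted(by_construct, key=construct_sort_key)
    fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(order)), 4))
    bp = ax.boxplot([by_construct[c] for c in order], tick_labels=order, whis=(0, 100),
                    patch_artist=True)
    for patch, c in zip(bp["boxes"], order):
        res = results.get(c)
        color = "lightgray"
        if res is not None:
            color = {"enhancer": "tomato", "silencer": "mediumseagreen"}.get(
                res.element_class, "lightgray"
            )
        patch.set_facecolor(color)
    ax.axhline(1.0, ls="--", lw=0.8, color="k")
    ax.set_ylabel("normalized firefly/Renilla ratio")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
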