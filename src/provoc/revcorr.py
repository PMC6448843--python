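"""Reverse-correlation analysis of two-interval forced-choice response tables.

A response set is a pandas DataFrame with one row per presented trial:

======================  =====================================================
column                  meaning
======================  =====================================================
``participant``         participant identifier
``trial``               trial index within participant (presentation order)
``A_0 .. A_{k-1}``      per-segment profile of interval A (cents or ratios)
``B_0 .. B_{k-1}``      per-segment profile of interval B
``choice``              'A' or 'B'
``pass_tag``            'main', or 'pass1'/'pass2' for the repeated block
======================  =====================================================

First-order kernels are the mean chosen profile minus the mean non-chosen
profile (optionally in the log domain for stretch ratios), normalized by the
absolute sum of their values.  Double-pass agreement over the repeated block
feeds a signal-detection model (late additive Gaussian noise plus response
criterion) whose Monte-Carlo lookup table converts (agreement, interval
bias) into an internal-noise SD expressed in external-noise units.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Kernel",
    "profile_columns",
    "read_response_table",
    "compute_first_order_kernel",
    "normalize_kernel",
    "rm_anova",
    "mixed_anova",
    "double_pass_agreement",
    "estimate_internal_noise",
    "InternalNoiseEstimate",
    "kernel_convergence",
]


@dataclass
class Kernel:
    """Per-participant first-order temporal kernel."""

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.normalized and abs(np.sum(np.abs(self.values)) - 1.0) > 1e-9:
            raise ValueError("normalized kernel must have unit absolute sum")


def profile_columns(frame: pd.DataFrame) -> tuple[list, list]:
    """The wide-format A_*/B_* profile columns, in segment order."""
    a_cols = sorted((c for c in frame.columns if c.startswith("A_")),
                    key=lambda c: int(c.split("_")[1]))
    b_cols = sorted((c for c in frame.columns if c.startswith("B_")),
                    key=lambda c: int(c.split("_")[1]))
    if not a_cols or len(a_cols) != len(b_cols):
        raise ValueError("response table must carry matching A_*/B_* profile columns")
    return a_cols, b_cols


def read_response_table(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a response CSV, optionally renaming foreign column layouts.

    ``column_map`` maps source column names to the canonical ones
    (participant, trial, choice, pass_tag, A_0..., B_0...).
    """
    frame = pd.read_csv(path)
    if column_map:
        frame = frame.rename(columns=column_map)
    if "pass_tag" not in frame.columns:
        frame["pass_tag"] = "main"
    if "trial" not in frame.columns:
        frame["trial"] = np.arange(len(frame))
    profile_columns(frame)  # validate
    return frame


def _chosen_split(frame: pd.DataFrame, domain: str):
    a_cols, b_cols = profile_columns(frame)
    a = frame[a_cols].to_numpy(dtype=np.float64)
    b = frame[b_cols].to_numpy(dtype=np.float64)
    if domain == "log":
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("log-domain kernels require strictly positive profiles")
        a, b = np.log(a), np.log(b)
    elif domain != "linear":
        raise ValueError(f"unknown domain {domain!r}")
    chose_a = frame["choice"].to_numpy() == "A"
    sel = np.where(chose_a[:, None], a, b)
    non = np.where(chose_a[:, None], b, a)
    return sel, non


def compute_first_order_kernel(frame: pd.DataFrame, domain: str = "linear") -> Kernel:
    """Mean chosen profile minus mean non-chosen profile, per segment."""
    if len(frame) == 0:
        raise ValueError("empty response set")
    sel, non = _chosen_split(frame, domain)
    return Kernel(sel.mean(axis=0) - non.mean(axis=0))


def normalize_kernel(kernel: Kernel) -> Kernel:
    """Divide by the absolute sum of the values."""
    total = np.sum(np.abs(kernel.values))
    if total == 0:
        raise ValueError("cannot normalize an all-zero kernel")
    return Kernel(kernel.values / total, normalized=True)


# ---------------------------------------------------------------------------
# ANOVA


def rm_anova(matrix) -> tuple[float, tuple[int, int], float]:
    """One-way repeated-measures ANOVA on a (participants x segments) matrix.

    F = MS_segment / MS_(segment x subject), df = (s-1), (s-1)(n-1).
    """
    x = np.asarray(matrix, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a complete matrix with >= 2 participants and >= 2 segments")
    if not np.all(np.isfinite(x)):
        raise ValueError("matrix contains missing or non-finite cells")
    n, s = x.shape
    grand = x.mean()
    ss_subj = s * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_seg = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_seg
    df_seg = s - 1
    df_err = (s - 1) * (n - 1)
    ms_seg = ss_seg / df_seg
    ms_err = ss_err / df_err
    f = ms_seg / ms_err if ms_err > 0 else 0.0
    p = float(stats.f.sf(f, df_seg, df_err))
    return float(f), (df_seg, df_err), p


def mixed_anova(matrix, group_labels) -> dict:
    """Split-plot ANOVA: within factor = segment, between factor = group.

    Returns a dict with F, df and p for the within main effect and the
    segment-by-group interaction.
    """
    x = np.asarray(matrix, dtype=np.float64)
    groups = np.asarray(group_labels)
    if x.ndim != 2 or len(groups) != x.shape[0]:
        raise ValueError("group_labels must give one label per participant row")
    levels = np.unique(groups)
    if len(levels) != 2 or any(np.sum(groups == g) < 2 for g in levels):
        raise ValueError("need exactly two groups with >= 2 members each")
    n, b = x.shape
    a = len(levels)
    grand = x.mean()
    subj_means = x.mean(axis=1)
    seg_means = x.mean(axis=0)

    ss_total = np.sum((x - grand) ** 2)
    ss_subj = b * np.sum((subj_means - grand) ** 2)
    ss_group = b * sum(np.sum(groups == g) * (subj_means[groups == g].mean() - grand) ** 2
                       for g in levels)
    ss_within = ss_total - ss_subj
    ss_seg = n * np.sum((seg_means - grand) ** 2)
    ss_inter = 0.0
    for g in levels:
        rows = x[groups == g]
        cell = rows.mean(axis=0)
        g_mean = rows.mean()
        ss_inter += len(rows) * np.sum((cell - g_mean - seg_means + grand) ** 2)
    ss_err_within = ss_within - ss_seg - ss_inter

    df_seg = b - 1
    df_err = (b - 1) * (n - a)
    ms_err = ss_err_within / df_err
    f_seg = (ss_seg / df_seg) / ms_err if ms_err > 0 else 0.0
    f_inter = (ss_inter / ((a - 1) * (b - 1))) / ms_err if ms_err > 0 else 0.0
    return {
        "within": {"F": float(f_seg), "df": (df_seg, df_err),
                   "p": float(stats.f.sf(f_seg, df_seg, df_err))},
        "interaction": {"F": float(f_inter), "df": ((a - 1) * (b - 1), df_err),
                        "p": float(stats.f.sf(f_inter, (a - 1) * (b - 1), df_err))},
    }


# ---------------------------------------------------------------------------
# Double pass & internal noise


def double_pass_agreement(frame: pd.DataFrame) -> tuple[float, float]:
    """Agreement over the repeated block and overall interval-A rate.

    Repeat trials carry pass tags 'pass1' and 'pass2' and pair one-to-one in
    presentation order within each tag.
    """
    p1 = frame[frame["pass_tag"] == "pass1"].sort_values("trial")
    p2 = frame[frame["pass_tag"] == "pass2"].sort_values("trial")
    if len(p1) == 0 or len(p1) != len(p2):
        raise ValueError("repeat trials must pair one-to-one across passes")
    agreement = float(np.mean(p1["choice"].to_numpy() == p2["choice"].to_numpy()))
    bias = float(np.mean(frame["choice"].to_numpy() == "A"))
    return agreement, bias


@dataclass
class InternalNoiseEstimate:
    sigma: float
    criterion: float
    reliable: bool


@lru_cache(maxsize=4)
def _double_pass_table(sigma_step: float = 0.05, sigma_max: float = 5.0,
                       bias_step: float = 0.05, bias_max: float = 2.0,
                       n_mc: int = 100_000, seed: int = 20190404):
    """Monte-Carlo (agreement, p_A) surface of the 2-interval SDT model.

    The observer model adds late noise of SD sigma (single-interval
    external-noise units) to the evidence difference, whose external part has
    variance 2; on the unit-variance normalized difference used here the
    late-noise SD is therefore sigma/sqrt(2).  Decisions threshold the
    variable at criterion b.  Common random numbers across the grid.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n_mc)
    e1 = rng.standard_normal(n_mc)
    e2 = rng.standard_normal(n_mc)
    sigmas = np.round(np.arange(0.0, sigma_max + 1e-9, sigma_step), 10)
    biases = np.round(np.arange(0.0, bias_max + 1e-9, bias_step), 10)
    agree = np.empty((len(sigmas), len(biases)))
    prob_a = np.empty_like(agree)
    for i, s in enumerate(sigmas):
        late = s / np.sqrt(2.0)
        d1 = x + late * e1
        d2 = x + late * e2
        c1 = d1[:, None] > biases[None, :]
        c2 = d2[:, None] > biases[None, :]
        agree[i] = np.mean(c1 == c2, axis=0)
        prob_a[i] = 0.5 * (np.mean(c1, axis=0) + np.mean(c2, axis=0))
    return sigmas, biases, agree, prob_a


def estimate_internal_noise(agreement: float, interval_bias: float) -> InternalNoiseEstimate:
    """Invert the double-pass SDT lookup table.

    Returns the internal-noise SD (in external-noise units) and criterion
    whose predicted (agreement, interval bias) lie nearest the observed pair.
    Estimates at agreement below chance consistency (0.5) are flagged
    unreliable.
    """
    if not (0.0 <= agreement <= 1.0 and 0.0 <= interval_bias <= 1.0):
        raise ValueError("agreement and bias must lie in [0, 1]")
    sigmas, biases, agree, prob_a = _double_pass_table()
    # the model is symmetric in the criterion sign; fold the observed bias
    pa = min(interval_bias, 1.0 - interval_bias)
    dist = (agree - agreement) ** 2 + (prob_a - pa) ** 2
    i, j = np.unravel_index(np.argmin(dist), dist.shape)
    crit = float(biases[j]) if interval_bias <= 0.5 else -float(biases[j])
    return InternalNoiseEstimate(
        sigma=float(sigmas[i]),
        criterion=crit,
        reliable=bool(agreement >= 0.5),
    )


# ---------------------------------------------------------------------------
# Convergence diagnostics


def kernel_convergence(frame: pd.DataFrame, step: int, domain: str = "linear"):
    """Pearson correlation of partial kernels against the full-data kernel.

    Returns an array of (n, r) rows for n = step, 2*step, ..., N.
    """
    if step < 1 or len(frame) < 2 * step:
        raise ValueError("need at least 2*step trials")
    ordered = frame.sort_values("trial")
    full = compute_first_order_kernel(ordered, domain).values
    if np.allclose(full, full[0]):
        raise ValueError("degenerate (constant) kernel: correlation undefined")
    ns = list(range(step, len(ordered) + 1, step))
    if ns[-1] != len(ordered):
        ns.append(len(ordered))
    out = []
    for n in ns:
        partial = compute_first_order_kernel(ordered.iloc[:n], domain).values
        r = float(np.corrcoef(partial, full)[0, 1])
        out.append((n, r))
    return np.asarray(out)
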