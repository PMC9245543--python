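"""Study orchestration: per-subject aggregation and between-state tests.

Per subject and state, metrics are averaged epochs-then-ROIs: per-ROI
values are means over the selected epochs; global values are means of the
regional values over all ROIs.  States are then compared across subjects
with two-sided paired t-tests on the global metrics, and per-ROI paired
t-tests corrected for the number of regions with the Benjamini-Hochberg
false discovery rate (significance: q < 0.05).

Subjects lacking the required number of epochs in either state of a
contrast are excluded listwise from that contrast, with a logged reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .connectivity import connectivity_matrix, global_and_regional_fc
from .core_io import (
    ArgumentError,
    BandDefinition,
    DegenerateInputError,
    Epoch,
    PipelineConfig,
    Recording,
    StateLabel,
    VigilnetError,
    logger,
    segment_epochs,
)
from .network import mst_from_connectivity, summarize_tree
from .spectral import aggregate_spectral, band_power_table


class EmptyStudyError(VigilnetError):
    """No subject satisfies the epoch-sufficiency requirement."""


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test on subject-matched values.

    Identical inputs give (0.0, 1.0).  Nonzero differences with exactly
    zero spread have no finite t statistic and raise
    :class:`DegenerateInputError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ArgumentError("paired samples must be 1-D and equal length")
    if len(x) < 2:
        raise ArgumentError("need at least 2 pairs")
    d = x - y
    if np.all(d == 0):
        return 0.0, 1.0
    if d.std(ddof=1) == 0:
        raise DegenerateInputError(
            "all paired differences identical and nonzero: t undefined"
        )
    t, p = scipy.stats.ttest_rel(x, y)
    return float(t), float(p)


def fdr_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ArgumentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# per-subject aggregation


@dataclass
class SubjectStateSummary:
    """Epoch-averaged metrics of one subject in one state."""

    subject_id: str
    state: StateLabel
    global_metrics: dict[str, float]
    regional_metrics: dict[str, np.ndarray]
    n_epochs: int


@dataclass
class Subject:
    """One subject's recording plus per-epoch state labels."""

    subject_id: str
    recording: Recording
    labels: list[StateLabel]


def summarize_subject_state(
    subject_id: str,
    epochs: list[Epoch],
    state: StateLabel,
    config: PipelineConfig,
    fc_bands: Sequence[BandDefinition],
    measures: Sequence[str],
) -> SubjectStateSummary:
    """Average one subject's selected epochs of one state."""
    tables = [band_power_table(ep, config) for ep in epochs]
    regional_power, global_power, regional_peak, global_peak = aggregate_spectral(tables)

    global_metrics: dict[str, float] = {
        f"power_{b}": float(global_power[b]) for b in regional_power.columns
    }
    global_metrics["peak_frequency"] = global_peak
    regional_metrics: dict[str, np.ndarray] = {
        f"power_{b}": regional_power[b].to_numpy() for b in regional_power.columns
    }
    regional_metrics["peak_frequency"] = regional_peak.to_numpy()

    for band in fc_bands:
        for measure in measures:
            g_vals, r_vals, lf_vals, th_vals, bcmax_vals, bc_vals = [], [], [], [], [], []
            for ep in epochs:
                cm = connectivity_matrix(ep, band, measure, config)
                g, r = global_and_regional_fc(cm)
                g_vals.append(g)
                r_vals.append(r)
                summ = summarize_tree(mst_from_connectivity(cm))
                lf_vals.append(summ.leaf_fraction)
                th_vals.append(summ.tree_hierarchy)
                bcmax_vals.append(summ.bc_max)
                bc_vals.append(summ.bc)
            key = f"{measure}_{band.name}"
            global_metrics[f"fc_{key}"] = float(np.mean(g_vals))
            global_metrics[f"mst_lf_{key}"] = float(np.mean(lf_vals))
            global_metrics[f"mst_th_{key}"] = float(np.mean(th_vals))
            global_metrics[f"mst_bcmax_{key}"] = float(np.mean(bcmax_vals))
            regional_metrics[f"fc_{key}"] = np.mean(r_vals, axis=0)
            regional_metrics[f"bc_{key}"] = np.mean(bc_vals, axis=0)

    return SubjectStateSummary(
        subject_id=subject_id,
        state=state,
        global_metrics=global_metrics,
        regional_metrics=regional_metrics,
        n_epochs=len(epochs),
    )


def summarize_subject(
    subject: Subject,
    config: PipelineConfig,
    fc_bands: Sequence[BandDefinition] = (),
    measures: Sequence[str] = ("PLI", "AECc"),
    states: Sequence[StateLabel] = (StateLabel.EO, StateLabel.A_EC, StateLabel.D_EC),
) -> dict[StateLabel, SubjectStateSummary] | None:
    """Epoch-averaged summaries of one subject for every requested state.

    Uses the first ``n_epochs_per_state`` epochs of each state; returns
    None (with a logged reason) when any requested state falls short.
    """
    epochs = segment_epochs(subject.recording, config.epoch_length)
    if len(epochs) != len(subject.labels):
        raise ArgumentError(
            f"subject {subject.subject_id}: {len(subject.labels)} labels for "
            f"{len(epochs)} epochs"
        )
    by_state: dict[StateLabel, list[Epoch]] = {s: [] for s in states}
    for ep, lab in zip(epochs, subject.labels):
        if lab in by_state:
            ep.state = lab
            by_state[lab].append(ep)
    need = config.n_epochs_per_state
    for s in states:
        if len(by_state[s]) < need:
            logger.info(
                "dropping subject %s: only %d %s epochs (need %d)",
                subject.subject_id, len(by_state[s]), s.value, need,
            )
            return None
    return {
        s: summarize_subject_state(
            subject.subject_id, by_state[s][:need], s, config, fc_bands, measures
        )
        for s in states
    }


# ---------------------------------------------------------------------------
# contrasts


CONTRASTS: dict[str, tuple[StateLabel, StateLabel]] = {
    "A_EC_vs_EO": (StateLabel.A_EC, StateLabel.EO),
    "A_EC_vs_D_EC": (StateLabel.A_EC, StateLabel.D_EC),
}


@dataclass
class ComparisonResult:
    """One metric compared between two states across subjects."""

    contrast: str
    metric: str
    t_statistic: float
    p_value: float
    n_subjects: int
    mean_a: float
    mean_b: float
    regional_p: np.ndarray | None = None
    regional_q: np.ndarray | None = None
    significant_rois: list[int] = field(default_factory=list)

    @property
    def regional_difference(self) -> bool:
        return len(self.significant_rois) > 0


@dataclass
class StudyResult:
    """Full study output: per-state group tables and contrast results."""

    table1: pd.DataFrame      # spectral + global FC: mean (SD) per state + p
    table2: pd.DataFrame      # MST metrics per measure/band
    comparisons: dict[tuple[str, str], ComparisonResult]
    n_subjects: int
    dropped_subjects: list[str]
    manifest: dict


#: Regional tests are run for these metric prefixes (power, peak frequency,
#: regional FC and regional BC).
_REGIONAL_PREFIXES = ("power_", "peak_frequency", "fc_", "bc_")


def run_study(
    subjects: Sequence[Subject],
    config: PipelineConfig | None = None,
    fc_bands: Sequence[BandDefinition] = (),
    measures: Sequence[str] = ("PLI", "AECc"),
    states: Sequence[StateLabel] | None = None,
) -> StudyResult:
    """Run the full between-state comparison on a cohort.

    ``fc_bands`` selects the bands in which connectivity and MST metrics
    are computed (empty: spectral analysis only).  ``states`` defaults to
    the states present in the subjects' labels (intersected with
    EO/A-EC/D-EC).  Raises :class:`EmptyStudyError` when no subject has
    enough epochs.
    """
    config = config or PipelineConfig()
    if states is None:
        present = {lab for s in subjects for lab in s.labels}
        states = [s for s in (StateLabel.EO, StateLabel.A_EC, StateLabel.D_EC)
                  if s in present]
    if not states:
        raise EmptyStudyError("no analyzable states present in the cohort")
    summaries: dict[str, dict[StateLabel, SubjectStateSummary]] = {}
    dropped: list[str] = []
    for subj in subjects:
        summ = summarize_subject(subj, config, fc_bands, measures, states)
        if summ is None:
            dropped.append(subj.subject_id)
        else:
            summaries[subj.subject_id] = summ
    if not summaries:
        raise EmptyStudyError("no subject has enough epochs in every state")

    ids = sorted(summaries)
    metrics = list(next(iter(summaries.values()))[states[0]].global_metrics)

    comparisons: dict[tuple[str, str], ComparisonResult] = {}
    for cname, (sa, sb) in CONTRASTS.items():
        if sa not in states or sb not in states:
            continue
        for metric in metrics:
            xa = np.array([summaries[i][sa].global_metrics[metric] for i in ids])
            xb = np.array([summaries[i][sb].global_metrics[metric] for i in ids])
            t, p = paired_t(xa, xb)
            result = ComparisonResult(
                contrast=cname, metric=metric, t_statistic=t, p_value=p,
                n_subjects=len(ids),
                mean_a=float(xa.mean()), mean_b=float(xb.mean()),
            )
            if metric.startswith(_REGIONAL_PREFIXES):
                key = metric if not metric.startswith("fc_") else metric
                ra = np.stack([summaries[i][sa].regional_metrics[key] for i in ids])
                rb = np.stack([summaries[i][sb].regional_metrics[key] for i in ids])
                p_reg = np.ones(ra.shape[1])
                for r in range(ra.shape[1]):
                    try:
                        _, p_reg[r] = paired_t(ra[:, r], rb[:, r])
                    except DegenerateInputError:
                        p_reg[r] = 1.0
                q_reg = fdr_adjust(p_reg)
                result.regional_p = p_reg
                result.regional_q = q_reg
                result.significant_rois = list(
                    np.flatnonzero(q_reg < config.alpha_level)
                )
            comparisons[(cname, metric)] = result

    table1, table2 = _build_tables(summaries, ids, states, metrics, comparisons)
    manifest = {
        "config": config.to_dict(),
        "n_subjects": len(ids),
        "subjects": ids,
        "dropped_subjects": dropped,
        "states": [s.value for s in states],
        "fc_bands": [b.name for b in fc_bands],
        "measures": list(measures),
    }
    return StudyResult(
        table1=table1, table2=table2, comparisons=comparisons,
        n_subjects=len(ids), dropped_subjects=dropped, manifest=manifest,
    )


def _build_tables(summaries, ids, states, metrics, comparisons):
    """Group mean (SD) per metric and state plus contrast p-values and
    regional flags, split into a spectral/FC table and an MST table."""
    rows1, rows2 = [], []
    for metric in metrics:
        row: dict[str, object] = {"metric": metric}
        for s in states:
            vals = np.array([summaries[i][s].global_metrics[metric] for i in ids])
            row[f"mean_{s.value}"] = vals.mean()
            row[f"sd_{s.value}"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        for cname in CONTRASTS:
            res = comparisons.get((cname, metric))
            if res is not None:
                row[f"p_{cname}"] = res.p_value
                if res.regional_p is not None:
                    row[f"regional_{cname}"] = "Yes" if res.regional_difference else "No"
        (rows2 if metric.startswith("mst_") else rows1).append(row)
    t1 = pd.DataFrame(rows1).set_index("metric") if rows1 else pd.DataFrame()
    t2 = pd.DataFrame(rows2).set_index("metric") if rows2 else pd.DataFrame()
    return t1, t2


# ---------------------------------------------------------------------------
# synthetic cohorts


def simulate_cohort(
    n_subjects: int,
    profiles_by_state: dict[StateLabel, "object"] | None = None,
    config: PipelineConfig | None = None,
    seed: int = 0,
    roi_labels: tuple[str, ...] | None = None,
    couplings: list | None = None,
    n_epochs_per_state: int | None = None,
    with_eog: bool = False,
) -> list[Subject]:
    """Generate a cohort of labelled synthetic subjects.

    Each subject gets an independent child seed derived from ``seed``.
    ``profiles_by_state`` maps the desired state labels to the generating
    profile (defaults: the standard alert/drowsy/eyes-open profiles); a
    *null* cohort is obtained by generating every state from the same
    profile while keeping the labels distinct.
    """
    from .core_io import AAL78_LABELS
    from .synthetic import default_profiles, generate_recording

    config = config or PipelineConfig()
    roi_labels = roi_labels if roi_labels is not None else AAL78_LABELS
    n_ep = n_epochs_per_state or config.n_epochs_per_state
    if profiles_by_state is None:
        profiles_by_state = default_profiles()
    child_seeds = np.random.SeedSequence(seed).spawn(n_subjects)
    subjects = []
    for k, child in enumerate(child_seeds):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        profile_list = [(prof, n_ep) for prof in profiles_by_state.values()]
        rec, _ = generate_recording(
            profile_list, couplings, config, seed=sub_seed,
            roi_labels=roi_labels, subject_id=f"sim{k:03d}", with_eog=with_eog,
        )
        labels = [state for state in profiles_by_state for _ in range(n_ep)]
        subjects.append(Subject(subject_id=f"sim{k:03d}", recording=rec,
                                labels=labels))
    return subjects
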