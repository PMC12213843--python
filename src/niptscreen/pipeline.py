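"""End-to-end orchestration: panels -> cohort -> counts -> calls -> outcomes.

Glue between the generator and the caller used by the CLI, the evaluation
helpers, and the calibration checks. Bin-resolution simulation is performed
only for samples whose placental state carries a sub-chromosomal CNV; all
other samples are simulated (and called) at chromosome resolution, which
leaves the aneuploidy statistics untouched and keeps cohort-scale runs cheap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_reference import ChromosomeMap, ReferencePanel, build_reference_panel
from .nipt_caller import CallThresholds, NIPTCall, ZScoreResult, screen_sample
from .performance_stats import PerformanceTable, evaluate_cohort
from .synthetic_cohort import (
    CohortConfig,
    FollowupConfig,
    GenomeBaseline,
    OutcomeRecord,
    SimulatedCase,
    expected_proportions,
    sample_cohort,
    simulate_counts,
    simulate_followup,
    simulate_reference_profiles,
)

__all__ = ["ScreenRun", "build_panels", "screen_cohort", "run_simulation"]

DEFAULT_DEPTH = 8_000_000
DEFAULT_N_REF = 100


def build_panels(
    config: CohortConfig,
    baseline: GenomeBaseline,
    rng: np.random.Generator,
    n_ref: int = DEFAULT_N_REF,
    depth: int = DEFAULT_DEPTH,
    bins: bool = False,
) -> dict[str, ReferencePanel]:
    """Sex-stratified reference panels from simulated euploid pregnancies."""
    panels = {}
    for sex, stratum in (("female", "female_fetus"), ("male", "male_fetus")):
        profiles = simulate_reference_profiles(
            n_ref, sex, config, depth, rng, baseline, bins=bins
        )
        panels[sex] = build_reference_panel(profiles, baseline.cmap, sex_stratum=stratum)
    return panels


@dataclass
class ScreenRun:
    """Everything one simulated screen produced, object- and table-level."""

    cases: list[SimulatedCase]
    zres: list[ZScoreResult]
    calls: list[NIPTCall]
    outcomes: list[OutcomeRecord]
    counts: np.ndarray | None = None  # (n_cases, n_chroms) final simulated counts
    panels: dict[str, ReferencePanel] | None = None

    def evaluated_pairs(self):
        """(call, fetal truth) pairs entering performance denominators.

        Excludes no-calls and positives never confirmed (amniocentesis
        refused without postnatal testing).
        """
        pairs = []
        for case, call, rec in zip(self.cases, self.calls, self.outcomes):
            if call.result == "no_call":
                continue
            if call.result == "positive" and rec.confirmed == "not_applicable":
                continue
            pairs.append((call, case.fetal_state))
        return pairs

    def performance(self) -> PerformanceTable:
        calls, truths = zip(*self.evaluated_pairs())
        return evaluate_cohort(list(calls), list(truths))

    # -- tabular views ------------------------------------------------------
    def cohort_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case_id": [c.case_id for c in self.cases],
                "maternal_age": [round(c.maternal_age, 2) for c in self.cases],
                "gestational_age": [round(c.gestational_age, 2) for c in self.cases],
                "fetal_sex": [c.fetal_sex for c in self.cases],
                "fetal_state": [c.fetal_state.to_string() for c in self.cases],
                "placental_state": [c.placental_state.to_string() for c in self.cases],
                "fetal_fraction": [round(c.fetal_fraction, 5) for c in self.cases],
                "redraw_flag": [c.redraw_flag for c in self.cases],
            }
        )

    def calls_frame(self) -> pd.DataFrame:
        rows = []
        for case, z, call in zip(self.cases, self.zres, self.calls):
            rows.append(
                {
                    "sample_id": case.case_id,
                    "result": call.result,
                    "category": ";".join(item.to_string() for item in call.calls),
                    "affected": ";".join(
                        item.chrom or "" for item in call.calls
                    ),
                    "z_values": json.dumps(
                        {k: round(v, 3) for k, v in call.evidence.items()}
                    ),
                    "ff_estimate": round(z.ff_estimate, 5)
                    if not np.isnan(z.ff_estimate)
                    else "",
                    "ff_method": z.ff_method,
                    "qc_status": "no_call" if call.result == "no_call" else z.qc_status,
                }
            )
        return pd.DataFrame(rows)

    def outcomes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case_id": [o.case_id for o in self.outcomes],
                "amniocentesis": [o.amniocentesis for o in self.outcomes],
                "confirmed": [o.confirmed for o in self.outcomes],
                "outcome": [o.outcome for o in self.outcomes],
            }
        )


def screen_cohort(
    cases: list[SimulatedCase],
    panels: dict[str, ReferencePanel],
    baseline: GenomeBaseline,
    rng: np.random.Generator,
    depth: int = DEFAULT_DEPTH,
    thresholds: CallThresholds = CallThresholds(),
    followup: FollowupConfig | None = None,
) -> ScreenRun:
    """Simulate counts and screen every case, then run the follow-up cascade.

    QC redraw budget: a case whose FF estimate fails QC gets one fresh count
    simulation (a second blood draw) unless its cohort-level redraw budget is
    already spent, after which it is a no-call.
    """
    followup = followup or FollowupConfig()
    cmap = baseline.cmap
    zres_list: list[ZScoreResult] = []
    calls: list[NIPTCall] = []
    outcomes: list[OutcomeRecord] = []
    count_rows: list[np.ndarray] = []
    bins_available = panels["female"].has_bins and panels["male"].has_bins

    for case in cases:
        level = (
            "bin"
            if (case.placental_state.category == "CNV" and bins_available)
            else "chrom"
        )
        expected = expected_proportions(
            case.placental_state, case.fetal_fraction, baseline, case.fetal_sex, level=level
        )
        profile = simulate_counts(expected, depth, rng, cmap)
        zres, call = screen_sample(
            profile, panels, baseline, thresholds, true_ff=case.fetal_fraction
        )
        if call is None and not case.redraw_flag:
            profile = simulate_counts(expected, depth, rng, cmap)  # one redraw
            zres, call = screen_sample(
                profile, panels, baseline, thresholds, true_ff=case.fetal_fraction
            )
        if call is None:
            call = NIPTCall(result="no_call")
        zres_list.append(zres)
        calls.append(call)
        count_rows.append(profile.chrom_counts)
        outcomes.append(simulate_followup(call, case, followup, rng))

    return ScreenRun(
        cases=cases,
        zres=zres_list,
        calls=calls,
        outcomes=outcomes,
        counts=np.stack(count_rows) if count_rows else None,
        panels=panels,
    )


def run_simulation(
    config: CohortConfig,
    n: int,
    seed: int,
    depth: int = DEFAULT_DEPTH,
    n_ref: int = DEFAULT_N_REF,
    bin_size: int = 100_000,
    thresholds: CallThresholds = CallThresholds(),
    followup: FollowupConfig | None = None,
    bins: bool | None = None,
) -> ScreenRun:
    """Full simulated screen of ``n`` pregnancies from a single seed."""
    rng = np.random.default_rng(seed)
    cmap = ChromosomeMap.grch37(bin_size=bin_size)
    baseline = GenomeBaseline.from_map(cmap)
    if bins is None:
        bins = config.prev_cnv > 0 or (
            config.cpm_fp_rate > 0 and config.cpm_fp_weights.get("CNV", 0) > 0
        )
    panels = build_panels(config, baseline, rng, n_ref=n_ref, depth=depth, bins=bins)
    cases = sample_cohort(config, n, rng, cmap)
    return screen_cohort(
        cases, panels, baseline, rng, depth=depth, thresholds=thresholds, followup=followup
    )
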