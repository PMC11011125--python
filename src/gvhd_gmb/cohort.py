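"""Published cohort composition used to calibrate the synthetic generator.

The study cohort is a single-center series of allogeneic HSCT recipients with
targeted bone-marrow RNA panels measured before and/or after transplantation.
The counts below are transcribed from the published patient-characteristics
table and are the package's calibration anchors: the synthetic generator's
default sample size and case prevalence derive from them, and the worked
examples recompute the prevalences from these counts rather than hard-coding
percentages.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CohortComposition:
    """Patient counts for one sampling timepoint."""

    n_patients: int
    n_agvhd: int          # grade 1-4 acute GvHD, any stage
    n_alive: int | None   # alive at analysis; None where not broken out

    @property
    def agvhd_prevalence(self) -> float:
        return self.n_agvhd / self.n_patients

    @property
    def survival_rate(self) -> float | None:
        if self.n_alive is None:
            return None
        return self.n_alive / self.n_patients


#: All patients with at least one usable sample.
OVERALL = CohortComposition(n_patients=167, n_agvhd=109, n_alive=None)

#: Patients with a pre-transplant marrow sample.
PRE_TRANSPLANT = CohortComposition(n_patients=132, n_agvhd=87, n_alive=None)

#: Patients with a post-transplant marrow sample (87 alive at follow-up).
POST_TRANSPLANT = CohortComposition(n_patients=119, n_agvhd=80, n_alive=87)

#: Size of the targeted cancer-associated gene panel.
N_PANEL_GENES = 1408

#: Median onset of acute GvHD, days after transplant.
MEDIAN_AGVHD_ONSET_DAYS = 37.5

#: Nominal sequencing depth, fragments per sample.
NOMINAL_READS_PER_SAMPLE = 10_000_000
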