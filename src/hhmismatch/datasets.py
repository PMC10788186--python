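"""Reference contingency counts of the multicenter known-onset stroke cohort.

These are the observed counts of the 247-patient observational cohort on
which the two imaging rules were compared: eligibility ground truth (within
the 4.5 h window, or late with a positive automated perfusion mismatch)
against each rule's calls.  They are inputs for the evaluation stage — all
accuracy metrics are recomputed from them, never transcribed.
"""

from __future__ import annotations

from .diagnostics import ConfusionTable

#: stratum sizes: within 4.5 h / late-but-mismatch-positive / late negative
N_WITHIN_WINDOW = 197
N_LATE_MISMATCH = 22
N_LATE_NO_MISMATCH = 28
N_ELIGIBLE = N_WITHIN_WINDOW + N_LATE_MISMATCH          # 219
N_TOTAL = N_ELIGIBLE + N_LATE_NO_MISMATCH               # 247

#: positive calls of the hypoperfusion-hypodensity mismatch rule per stratum
HHM_POS_WITHIN_WINDOW = 190
HHM_POS_LATE_MISMATCH = 5
HHM_POS_LATE_NO_MISMATCH = 8

#: positive calls of the automated perfusion-mismatch rule per stratum
EXTEND_POS_WITHIN_WINDOW = 88
EXTEND_POS_LATE_MISMATCH = 22   # positive by definition of the stratum
EXTEND_POS_LATE_NO_MISMATCH = 0


def hhm_confusion() -> ConfusionTable:
    """HHM calls vs thrombolysis eligibility: (tp=195, fp=8, fn=24, tn=20)."""
    tp = HHM_POS_WITHIN_WINDOW + HHM_POS_LATE_MISMATCH
    fp = HHM_POS_LATE_NO_MISMATCH
    return ConfusionTable(tp=tp, fp=fp, fn=N_ELIGIBLE - tp,
                          tn=N_LATE_NO_MISMATCH - fp)


def extend_confusion() -> ConfusionTable:
    """Automated mismatch vs eligibility: (tp=110, fp=0, fn=109, tn=28)."""
    tp = EXTEND_POS_WITHIN_WINDOW + EXTEND_POS_LATE_MISMATCH
    fp = EXTEND_POS_LATE_NO_MISMATCH
    return ConfusionTable(tp=tp, fp=fp, fn=N_ELIGIBLE - tp,
                          tn=N_LATE_NO_MISMATCH - fp)
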