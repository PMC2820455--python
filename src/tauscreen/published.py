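"""The 27 published candidate-kinase rows from the original kinome screen.

The original screen report lists, per candidate siRNA, the mean cell count
and the triplicate average, sample SD and two-tailed p-value for each of
the three readouts: phospho-tau relative to non-silencing control
("phospho"), total tau relative to control ("total") and the phospho/total
ratio. Seventeen rows are phospho-specific candidates (significant phospho
and ratio change, no significant total-tau change) and ten are dual-effect
candidates (significant change in both channels); EIF2AK2 appears twice in
the dual-effect set because two independent siRNAs scored.

These printed numbers are inputs to the audit and hit-calling validation
surfaces; they are transcribed, not computed.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["published_hit_rows", "PHOSPHO_SPECIFIC", "DUAL_EFFECT"]

PHOSPHO_SPECIFIC = "phospho_specific"
DUAL_EFFECT = "dual_effect"

_ROWS = """\
table,gene,sirna_idx,cell_count,phospho_avg,phospho_sd,phospho_p,total_avg,total_sd,total_p,ratio_avg,ratio_sd,ratio_p
phospho_specific,MARK2,1,453,0.672,0.044,0.006,0.979,0.039,0.451,0.687,0.060,0.012
phospho_specific,PAK3,1,170,0.803,0.067,0.036,1.112,0.197,0.429,0.730,0.072,0.023
phospho_specific,PAK2,1,287,0.726,0.081,0.028,0.986,0.101,0.831,0.741,0.109,0.054
phospho_specific,ADCK5,1,280,0.716,0.104,0.042,0.934,0.094,0.351,0.765,0.069,0.028
phospho_specific,AKAP13,1,181,0.738,0.069,0.023,0.929,0.070,0.223,0.797,0.086,0.054
phospho_specific,LOC55971,1,152,0.836,0.035,0.014,0.982,0.019,0.241,0.852,0.042,0.026
phospho_specific,PLK2,1,335,0.774,0.087,0.046,0.906,0.114,0.289,0.856,0.052,0.040
phospho_specific,DYRK1A,1,316,0.774,0.051,0.017,0.848,0.104,0.127,0.860,0.038,0.023
phospho_specific,MAK,1,393,1.109,0.021,0.012,0.919,0.037,0.063,1.209,0.054,0.021
phospho_specific,ITK,1,285,1.124,0.036,0.027,0.887,0.059,0.079,1.273,0.118,0.057
phospho_specific,PIM1,1,409,1.248,0.097,0.047,0.965,0.105,0.624,1.297,0.080,0.023
phospho_specific,RAGE,1,397,1.305,0.106,0.038,0.960,0.088,0.511,1.361,0.053,0.007
phospho_specific,ITPK1,1,399,1.324,0.119,0.042,0.930,0.084,0.285,1.424,0.024,0.001
phospho_specific,CKB,1,223,1.537,0.143,0.023,1.065,0.146,0.523,1.454,0.138,0.030
phospho_specific,PFKM,1,375,1.305,0.096,0.032,0.888,0.112,0.227,1.476,0.082,0.010
phospho_specific,DGKB,1,440,1.350,0.096,0.024,0.921,0.163,0.488,1.489,0.200,0.052
phospho_specific,SPHK2,1,333,1.792,0.282,0.040,1.074,0.121,0.399,1.664,0.114,0.010
dual_effect,EIF2AK2,1,217,0.606,0.075,0.012,0.647,0.102,0.026,0.962,0.237,0.806
dual_effect,EIF2AK2,2,318,0.719,0.069,0.018,0.706,0.082,0.025,1.038,0.257,0.822
dual_effect,CDKL1,1,398,0.852,0.032,0.015,0.761,0.085,0.040,1.132,0.157,0.281
dual_effect,DCK,1,363,1.068,0.015,0.017,0.701,0.051,0.010,1.530,0.107,0.013
dual_effect,DGKQ,1,406,1.119,0.042,0.039,0.805,0.059,0.029,1.394,0.111,0.026
dual_effect,PFKFB3,1,458,1.204,0.046,0.016,0.813,0.029,0.008,1.483,0.088,0.011
dual_effect,ERK8,1,466,1.234,0.063,0.024,0.807,0.009,0.001,1.528,0.084,0.008
dual_effect,STK19,1,347,1.334,0.103,0.030,0.654,0.115,0.035,2.065,0.231,0.015
dual_effect,PRKG2,1,413,1.384,0.152,0.048,0.721,0.107,0.046,1.959,0.412,0.056
dual_effect,MAP2K1IP1,1,436,1.393,0.052,0.006,0.831,0.048,0.026,1.679,0.123,0.011
"""


def published_hit_rows() -> pd.DataFrame:
    """All 27 published candidate rows as one table.

    The ``table`` column records which published tier each row belongs to;
    ``sirna_idx`` disambiguates the two EIF2AK2 siRNAs. A ``sirna_id``
    column is synthesised for API compatibility with screen summaries.
    """
    df = pd.read_csv(io.StringIO(_ROWS))
    df["sirna_id"] = df["gene"] + "_s" + df["sirna_idx"].astype(str)
    return df
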