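"""Reference MR-PrLD records: the six top-ranking domains of the published
human census, used as worked calibration inputs.

Coordinates are canonical 1-based inclusive; ``x`` is the printed Met count
and ``p_value`` the printed binomial score.  The whole-protein Met
frequencies behind those scores are not part of the printed record, so the
p-values anchor ranking checks rather than bit-exact recomputation.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ReferenceDomain:
    accession: str
    start: int
    end: int
    length: int
    x: int
    p_value: float
    sequence: str


REFERENCE_DOMAINS: tuple[ReferenceDomain, ...] = (
    ReferenceDomain(
        "O75400", 65, 121, 57, 19, 1.79e-13,
        "PMGMHPMGQRANMPPVPHGMMPQMMPPMGGPPMGQMPGMMSSVMPGMMMSHMSQASM",
    ),
    ReferenceDomain(
        "Q8WYB5", 1961, 2068, 108, 21, 4.53e-13,
        "MQRGMNMSVNLMPAPAYNVNSVNMNMNTLNAMNGYSMSQPMMNSGYHSNHGYMNQTPQ"
        "YPMQMQMGMMGTQPYAQQPMQTPPHGNMMYTAPGHHGYMNTGMSKQSLNG",
    ),
    ReferenceDomain(
        "Q92794", 1894, 1977, 84, 18, 5.74e-12,
        "QRGMNMGVNLMPTPAYNVNSMNMNTLNAMNSYRMTQPMMNSSYHSNPAYMNQTAQYPM"
        "QMQMGMMGSQAYTQQPMQPNPHGNMM",
    ),
    ReferenceDomain(
        "Q96JP2", 820, 847, 28, 8, 6.25e-9,
        "PMVYPGMIQMPAYQPGMVPAPMPMMPAM",
    ),
    ReferenceDomain(
        "Q9UMZ2", 37, 94, 58, 12, 9.29e-9,
        "PPQAGLMPMQQQGFPMVSVMQPNMQGIMGMNYSSQMSQGPIAMQAGIPMGPMPAAGMP",
    ),
    ReferenceDomain(
        "Q14677", 549, 591, 43, 14, 1.72e-8,
        "MPMSMPNVMTGTMGMAPLGNTPMMNQSMMGMNMNIGMSAAGMG",
    ),
)

#: Summary values for the worked aggregation-class example (initiator
#: stripped): effective length and Met count of O75400, and its published
#: transect coefficient of variation.
O75400_EFFECTIVE_LENGTH = 956
O75400_MET_COUNT = 42
O75400_PUBLISHED_Q = 1.627
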