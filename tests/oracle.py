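"""Brute-force decision-tree oracle: explicit leaf enumeration.

Independent of the package's aggregated arithmetic: every tree leaf
(true state x amyloid x referral outcome x blood-test result x CSF result)
is enumerated with its joint probability and the intermediate outcomes are
accumulated leaf by leaf.
"""

from __future__ import annotations

from dataclasses import dataclass

from bbmcue.parameters import ParameterSet


@dataclass
class LeafTotals:
    referred: float = 0.0
    bbm_tested: float = 0.0
    csf: float = 0.0
    tp: float = 0.0
    tn: float = 0.0
    fp: float = 0.0
    fn: float = 0.0


def enumerate_leaves(pathway: str, params: ParameterSet) -> LeafTotals:
    pop, acc, pol = params.population, params.accuracy, params.policy
    totals = LeafTotals()

    cells = [
        ("SCD", pop.share_scd, pop.amyloid_prev_scd),
        ("MCI", pop.share_mci, pop.amyloid_prev_mci),
        ("MILD_DEM", pop.share_mild_dem, pop.amyloid_prev_dem),
    ]
    for state, share, prev in cells:
        for amypos, p_amy in ((True, prev), (False, 1.0 - prev)):
            cell_mass = share * p_amy

            def record(prob: float, referred: bool, bbm: bool, csf: bool,
                       diagnosed: bool) -> None:
                mass = cell_mass * prob
                totals.referred += mass * referred
                totals.bbm_tested += mass * bbm
                totals.csf += mass * csf
                if amypos and diagnosed:
                    totals.tp += mass
                elif amypos:
                    totals.fn += mass
                elif diagnosed:
                    totals.fp += mass
                else:
                    totals.tn += mass

            if state == "SCD":
                record(1.0, False, False, False, False)
                continue

            p_bbm_pos = acc.bbm_sensitivity if amypos else 1.0 - acc.bbm_specificity
            p_csf_pos = acc.csf_sensitivity if amypos else 1.0 - acc.csf_specificity

            if pathway == "SOC":
                for ref, p_ref in ((True, pol.soc_referral_rate),
                                   (False, 1.0 - pol.soc_referral_rate)):
                    if not ref:
                        record(p_ref, False, False, False, False)
                        continue
                    for csf_pos, p_c in ((True, p_csf_pos), (False, 1.0 - p_csf_pos)):
                        record(p_ref * p_c, True, False, True, csf_pos)
            elif pathway == "BBM_PHC":
                for bbm_pos, p_b in ((True, p_bbm_pos), (False, 1.0 - p_bbm_pos)):
                    if not bbm_pos:
                        record(p_b, False, True, False, False)
                        continue
                    for ref, p_ref in (
                        (True, pol.bbm_positive_referral_rate),
                        (False, 1.0 - pol.bbm_positive_referral_rate),
                    ):
                        if not ref:
                            record(p_b * p_ref, False, True, False, False)
                            continue
                        for csf_pos, p_c in ((True, p_csf_pos),
                                             (False, 1.0 - p_csf_pos)):
                            record(p_b * p_ref * p_c, True, True, True, csf_pos)
            elif pathway == "BBM_MC":
                for ref, p_ref in ((True, pol.soc_referral_rate),
                                   (False, 1.0 - pol.soc_referral_rate)):
                    if not ref:
                        record(p_ref, False, False, False, False)
                        continue
                    for bbm_pos, p_b in ((True, p_bbm_pos), (False, 1.0 - p_bbm_pos)):
                        if not bbm_pos:
                            record(p_ref * p_b, True, True, False, False)
                            continue
                        for csf_pos, p_c in ((True, p_csf_pos),
                                             (False, 1.0 - p_csf_pos)):
                            record(p_ref * p_b * p_c, True, True, True, csf_pos)
            else:
                raise ValueError(pathway)
    return totals
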