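"""Association report: carrier frequencies, exact tests over phenotype
strata, control-cohort odds ratios, and age comparisons."""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional

import numpy as np

from .consequence import ConsequenceKind
from .models import (
    ControlSummary,
    HDR_GENES,
    MMR_GENES,
    HpvStatus,
    PatientRecord,
    Stage,
)
from .stats import (
    ContingencyTable,
    DegenerateTableError,
    EnumerationBudgetError,
    aggregate_carriers,
    fisher_exact_2xk,
    group_mean_ci,
    median_test,
    odds_ratio,
)
from .triage import Klass

TRUNCATING = (ConsequenceKind.STOP_GAINED.value, ConsequenceKind.FRAMESHIFT.value)

#: Default HPV strata among invasive cases (positive types only).
HPV_STRATA = (HpvStatus.HPV16.value, HpvStatus.HPV18.value, HpvStatus.OTHER_POSITIVE.value)


def _strat_test(
    patients: List[PatientRecord],
    flags: Dict[str, bool],
    key,
    strata: Iterable[str],
) -> Optional[dict]:
    strata = list(strata)
    carr = [0] * len(strata)
    non = [0] * len(strata)
    for p in patients:
        val = key(p)
        if val not in strata:
            continue
        j = strata.index(val)
        if flags[p.patient_id]:
            carr[j] += 1
        else:
            non[j] += 1
    cols = [j for j in range(len(strata)) if carr[j] + non[j] > 0]
    if len(cols) < 2 or sum(carr) == 0 or sum(non) == 0:
        return None
    table = ContingencyTable(
        (tuple(carr[j] for j in cols), tuple(non[j] for j in cols)),
        row_labels=("carrier", "non_carrier"),
        col_labels=tuple(strata[j] for j in cols),
    )
    try:
        p_val = fisher_exact_2xk(table)
    except (DegenerateTableError, EnumerationBudgetError):
        return None
    return {
        "strata": list(table.col_labels),
        "carriers": list(table.counts[0]),
        "non_carriers": list(table.counts[1]),
        "df": table.df,
        "p_two_sided": p_val,
        "test": "Fisher exact (Freeman-Halton)",
    }


def _or_entry(a: int, na: int, b: int, nb: int) -> Optional[dict]:
    try:
        r = odds_ratio(a, na, b, nb)
    except (DegenerateTableError, ValueError):
        return None
    return {
        "carriers_a": a, "total_a": na, "carriers_b": b, "total_b": nb,
        "or": r.or_estimate, "ci_low": r.ci_low, "ci_high": r.ci_high,
        "p_two_sided": r.p_two_sided, "correction_applied": r.correction_applied,
    }


def association_report(
    patients: List[PatientRecord],
    classifications: Dict[str, dict],
    controls: Optional[List[ControlSummary]] = None,
    severity_floor: Klass = Klass.LIKELY_PATHOGENIC,
) -> dict:
    """Full association report over the configured stratifications.

    ``classifications`` maps variant id → dict with ``gene``,
    ``classification``, ``consequence``, ``in_last_exon`` (as produced
    by the triage engine's classified table). Control comparison pools
    carriers of truncating (non-last-exon) variants across the HDR gene
    set, with per-gene ORs flagged as low-power.
    """
    n = len(patients)
    report: dict = {"n_patients": n, "severity_floor": severity_floor.value}

    flag_sets = {
        "any": aggregate_carriers(patients, classifications, None, severity_floor),
        "hdr": aggregate_carriers(patients, classifications, HDR_GENES, severity_floor),
        "mmr": aggregate_carriers(patients, classifications, MMR_GENES, severity_floor),
        "hdr_truncating": aggregate_carriers(
            patients, classifications, HDR_GENES, severity_floor, kinds=TRUNCATING
        ),
    }
    report["carriers"] = {
        name: {
            "count": sum(f.values()),
            "frequency_percent": round(100.0 * sum(f.values()) / n, 1) if n else 0.0,
        }
        for name, f in flag_sets.items()
    }

    invasive = [p for p in patients if p.stage is Stage.INVASIVE]
    strat: dict = {}
    for name, flags in (("hdr", flag_sets["hdr"]), ("mmr", flag_sets["mmr"]),
                        ("hdr_truncating", flag_sets["hdr_truncating"])):
        entry: dict = {}
        t = _strat_test(patients, flags, lambda p: p.histology.value,
                        ("squamous", "adenocarcinoma", "other"))
        if t:
            entry["histology"] = t
        t = _strat_test(invasive, flags, lambda p: p.hpv.value, HPV_STRATA)
        if t:
            entry["hpv_invasive"] = t
        t = _strat_test(patients, flags, lambda p: p.stage.value,
                        ("dysplasia", "invasive"))
        if t:
            entry["stage"] = t
        # HPV18 vs other positive types, invasive cases
        hpv18_c = sum(1 for p in invasive if flags[p.patient_id]
                      and p.hpv is HpvStatus.HPV18)
        hpv18_t = sum(1 for p in invasive if flags[p.patient_id]
                      and p.hpv.value in HPV_STRATA)
        n18 = sum(1 for p in invasive if not flags[p.patient_id]
                  and p.hpv is HpvStatus.HPV18)
        nt = sum(1 for p in invasive if not flags[p.patient_id]
                 and p.hpv.value in HPV_STRATA)
        o = _or_entry(hpv18_c, hpv18_t, n18, nt) if hpv18_t and nt else None
        if o:
            entry["hpv18_or_invasive"] = o
        if entry:
            strat[name] = entry
    report["stratifications"] = strat

    # age comparisons among invasive cases
    ages: dict = {}
    inv_flags = {name: f for name, f in flag_sets.items()}
    non_ages = [p.age for p in invasive if not inv_flags["any"][p.patient_id]]
    for name in ("hdr", "mmr"):
        grp = [p.age for p in invasive if inv_flags[name][p.patient_id]]
        if len(grp) >= 2 and len(non_ages) >= 2:
            mean, lo, hi = group_mean_ci(grp)
            ages[name] = {
                "n": len(grp),
                "mean": mean, "ci_low": lo, "ci_high": hi,
                "median_test_p": median_test(grp, non_ages),
            }
    if len(non_ages) >= 2:
        mean, lo, hi = group_mean_ci(non_ages)
        ages["non_carriers"] = {"n": len(non_ages), "mean": mean,
                                "ci_low": lo, "ci_high": hi}
    report["age_invasive"] = ages

    # control-cohort comparison (pooled truncating-HDR carriers)
    if controls is not None:
        hdr_controls = [c for c in controls if c.gene in HDR_GENES or c.gene not in MMR_GENES]
        pooled_carriers = sum(c.carriers for c in hdr_controls)
        pooled_total = max((c.total for c in hdr_controls), default=0)
        case_carriers = sum(flag_sets["hdr_truncating"].values())
        entry = None
        if pooled_total > 0:
            entry = _or_entry(case_carriers, n, pooled_carriers, pooled_total)
        per_gene = {}
        for c in hdr_controls:
            flags = aggregate_carriers(
                patients, classifications, {c.gene}, severity_floor, kinds=TRUNCATING
            )
            o = _or_entry(sum(flags.values()), n, c.carriers, c.total)
            if o is not None:
                o["low_power"] = True
                per_gene[c.gene] = o
        report["control_comparison"] = {
            "pooled_truncating_hdr": entry,
            "per_gene": per_gene,
        }
    return report
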