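"""End-to-end cohort driver: phantoms -> rendering -> resampling -> volumetry.

Glue that turns a list of synthetic exams into the per-segment tables the
agreement layer consumes, following the protocol order: render both
modalities, rescale to the 0.5 mm isotropic analysis grid, then threshold
and measure within each segment ROI.
"""

from __future__ import annotations

import pandas as pd

from .phantom import Exam, render_ct, render_mr
from .quantify import ThresholdPolicy, quantify_exam, roi_from_definition
from .volume_io import ANALYSIS_SPACING_MM, CT, MR, resample_isotropic

__all__ = ["quantify_cohort", "pairs_from_tables"]


def quantify_cohort(
    exams: list[Exam],
    policy: ThresholdPolicy | None = None,
    target_mm: float = ANALYSIS_SPACING_MM,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render and quantify every exam of a cohort.

    Returns ``(segment_table, pairs)``: the long per-(segment, modality)
    table, and one row per segment pairing MR and CTA volumes with
    ground-truth totals and stratum labels — ready for
    :class:`~calcquant.agreement.AgreementAnalysis`.
    """
    policy = policy or ThresholdPolicy()
    tables = []
    pair_rows = []
    for exam in exams:
        ct_vol = resample_isotropic(render_ct(exam.spec), target_mm)
        mr_vol = resample_isotropic(render_mr(exam.spec), target_mm)
        rois = [roi_from_definition(d, ct_vol) for d in exam.roi_defs]
        table = quantify_exam(exam.exam_id, ct_vol, mr_vol, rois, policy)
        tables.append(table)
        truth = exam.truth.segment_totals(voxelized=True)
        wide = table.pivot(index="segment", columns="modality", values="volume_mm3")
        groups = table.drop_duplicates("segment").set_index("segment")["group"]
        for segment in wide.index:
            pair_rows.append(
                dict(
                    exam_id=exam.exam_id,
                    segment=segment,
                    mr_mm3=wide.loc[segment, MR],
                    cta_mm3=wide.loc[segment, CT],
                    truth_mm3=truth.get(segment, 0.0),
                    field=exam.field_strength,
                    region=exam.region,
                    group=int(groups.loc[segment]),
                )
            )
    segment_table = pd.concat(tables, ignore_index=True)
    pairs = pd.DataFrame(pair_rows)
    return segment_table, pairs


def pairs_from_tables(segment_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long segment table into per-segment (MR, CTA) volume pairs."""
    rows = []
    for (exam_id, segment), sub in segment_table.groupby(["exam_id", "segment"]):
        if sub["excluded"].astype(bool).any():
            continue
        by_mod = sub.set_index("modality")["volume_mm3"]
        rows.append(
            dict(
                exam_id=exam_id,
                segment=segment,
                mr_mm3=by_mod.get(MR),
                cta_mm3=by_mod.get(CT),
                group=int(sub["group"].iloc[0]),
            )
        )
    return pd.DataFrame(rows)
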