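"""The 36 manually-read radiographic grade features.

One Kellgren–Lawrence (KL) global grade (0–4) from the PA view plus 35
per-feature ordinal grades (OARSI-style, 0–1 or 0–3) read from the PA and
lateral (LA) views: osteophytes, joint space narrowing (JSN), sclerosis,
cysts, attrition, chondrocalcinosis, effusion and ossification features,
split by compartment (tibiofemoral TF / patellofemoral PF, medial/lateral)
and bone.

Each feature carries a default *severity loading* used by the synthetic
cohort generator: the weight with which the latent osteoarthritis severity
drives that grade.  Features that real readers score at chance with respect
to pain (chondrocalcinosis, cysts, attrition, tendon ossification) default
to loading zero; osteophytes, JSN and sclerosis carry moderate loadings and
the KL grade the strongest one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GradeFeature:
    name: str          # snake-case column name
    max_grade: int     # grades run 0..max_grade
    default_loading: float

    @property
    def n_levels(self) -> int:
        return self.max_grade + 1


# Order is the canonical reading-sheet order used everywhere downstream
# (cohort CSV columns, feature matrices, single-feature screens).
GRADE_FEATURES: tuple[GradeFeature, ...] = (
    GradeFeature("chondrocalcinosis_pf_la", 1, 0.00),
    GradeFeature("osteophytes_femur_anterior_pf_la", 3, 0.45),
    GradeFeature("osteophytes_femur_posterior_pf_la", 3, 0.55),
    GradeFeature("jsn_lateral_tf_la", 3, 0.30),
    GradeFeature("jsn_medial_tf_la", 3, 0.45),
    GradeFeature("effusion_pf_la", 1, 0.30),
    GradeFeature("kl_grade_pa", 4, 0.80),
    GradeFeature("chondrocalcinosis_lateral_tf_pa", 1, 0.00),
    GradeFeature("cyst_femur_lateral_tf_pa", 3, 0.00),
    GradeFeature("osteophytes_femur_lateral_tf_pa", 3, 0.55),
    GradeFeature("sclerosis_femur_lateral_tf_pa", 3, 0.30),
    GradeFeature("jsn_lateral_tf_pa", 3, 0.30),
    GradeFeature("attrition_lateral_tf_pa", 1, 0.00),
    GradeFeature("cyst_tibia_lateral_tf_pa", 3, 0.00),
    GradeFeature("osteophytes_tibia_lateral_tf_pa", 3, 0.55),
    GradeFeature("sclerosis_tibia_lateral_tf_pa", 3, 0.30),
    GradeFeature("chondrocalcinosis_medial_tf_pa", 1, 0.00),
    GradeFeature("cyst_femur_medial_tf_pa", 3, 0.00),
    GradeFeature("osteophytes_femur_medial_tf_pa", 3, 0.55),
    GradeFeature("sclerosis_femur_medial_tf_pa", 3, 0.45),
    GradeFeature("jsn_medial_tf_pa", 3, 0.45),
    GradeFeature("attrition_medial_tf_pa", 1, 0.15),
    GradeFeature("cyst_tibia_medial_tf_pa", 3, 0.00),
    GradeFeature("osteophytes_tibia_medial_tf_pa", 3, 0.45),
    GradeFeature("sclerosis_tibia_medial_tf_pa", 3, 0.45),
    GradeFeature("ossification_patella_tendon_lower_pf_la", 3, 0.00),
    GradeFeature("ossification_patella_tendon_upper_pf_la", 3, 0.00),
    GradeFeature("ossified_loose_body_femur_posterior_pf_la", 1, 0.15),
    GradeFeature("ossification_quadriceps_insertion_pf_la", 3, 0.00),
    GradeFeature("cyst_pf_la", 3, 0.00),
    GradeFeature("jsn_pf_la", 3, 0.15),
    GradeFeature("sclerosis_pf_la", 3, 0.15),
    GradeFeature("osteophytes_patella_inferior_pf_la", 3, 0.45),
    GradeFeature("osteophytes_patella_superior_pf_la", 3, 0.55),
    GradeFeature("osteophytes_tibia_anterior_pf_la", 3, 0.30),
    GradeFeature("osteophytes_tibia_posterior_pf_la", 3, 0.45),
)

N_GRADE_FEATURES = len(GRADE_FEATURES)
GRADE_COLUMNS = [f.name for f in GRADE_FEATURES]
DEFAULT_LOADINGS = np.array([f.default_loading for f in GRADE_FEATURES])

# Ordinal bin boundaries as marginal quantiles, by grade range.  Most knees
# grade 0, emulating the sparsity of OARSI-style reading.
DEFAULT_GRADE_QUANTILES: dict[int, tuple[float, ...]] = {
    1: (0.70,),
    3: (0.60, 0.85, 0.95),
    4: (0.45, 0.70, 0.85, 0.95),
}


def feature_by_name(name: str) -> GradeFeature:
    for f in GRADE_FEATURES:
        if f.name == name:
            return f
    raise KeyError(f"unknown grade feature {name!r}")
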