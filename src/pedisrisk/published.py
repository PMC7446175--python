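"""Published reference values for the single-centre DFU cohort this package models.

A prospective German wound-care-centre cohort of 237 diabetic-foot-ulcer (DFU)
patients, PEDIS-classified at baseline and followed for six months, reported
marginal stage counts per risk factor split by amputation status, together with
Bayesian logistic-regression summaries (posterior beta medians with 95% HDIs and
the exponentiated odds-ratio scale) for four models: any- vs major-amputation,
each with and without informative priors.

These numbers serve two roles here:

* defaults for :mod:`pedisrisk.synthetic_cohort` (marginal stage probabilities,
  age distribution, sex ratio, outcome prevalences, true-coefficient magnitudes);
* structural fixtures — e.g. the exact-arithmetic relations between the printed
  marginal counts and the printed PEDIS-sum means, and between printed betas and
  printed odds ratios.

The patient-level data behind these summaries were never published; nothing in
this module is a substitute for them.
"""

from __future__ import annotations

#: Study bookkeeping: 254 enrolled, 16 lost to follow-up, 237 analysed.
ENROLLED_N = 254
LOST_TO_FOLLOWUP_N = 16
COHORT_N = 237

#: Analysed-group sizes by outcome status.
GROUP_N = {
    "overall": 237,
    "any_nonamputee": 162,
    "any_amputee": 75,
    "major_nonamputee": 208,
    "major_amputee": 29,
}

#: Reported age summaries (years): mean, SD per group.
AGE_SUMMARY = {
    "overall": (65.91, 12.3),
    "any_nonamputee": (64.59, 12.8),
    "any_amputee": (68.76, 10.5),
    "major_nonamputee": (65.55, 12.5),
    "major_amputee": (68.52, 12.4),
}

#: Reported PEDIS sum-score summaries: mean, SD per group.
PEDIS_SUM_SUMMARY = {
    "overall": (10.76, 1.9),
    "any_nonamputee": (10.27, 1.9),
    "any_amputee": (11.81, 1.4),
    "major_nonamputee": (10.56, 1.9),
    "major_amputee": (12.17, 1.4),
}

#: Female/male counts per group.
GENDER_COUNTS = {
    "overall": {"female": 39, "male": 198},
    "any_nonamputee": {"female": 29, "male": 133},
    "any_amputee": {"female": 10, "male": 65},
    "major_nonamputee": {"female": 35, "male": 173},
    "major_amputee": {"female": 4, "male": 25},
}

#: Marginal stage counts per PEDIS risk factor and group; index i = grade i+1.
STAGE_COUNTS = {
    "perfusion": {
        "overall": (114, 77, 46),
        "any_nonamputee": (97, 48, 17),
        "any_amputee": (17, 29, 29),
        "major_nonamputee": (108, 66, 34),
        "major_amputee": (6, 11, 12),
    },
    "extent": {
        "overall": (8, 74, 155),
        "any_nonamputee": (8, 67, 87),
        "any_amputee": (0, 7, 68),
        "major_nonamputee": (8, 72, 128),
        "major_amputee": (0, 2, 27),
    },
    "depth": {
        "overall": (14, 78, 145),
        "any_nonamputee": (12, 67, 83),
        "any_amputee": (2, 11, 62),
        "major_nonamputee": (14, 75, 119),
        "major_amputee": (0, 3, 26),
    },
    "infection": {
        "overall": (86, 84, 61, 6),
        "any_nonamputee": (62, 54, 43, 3),
        "any_amputee": (24, 30, 18, 3),
        "major_nonamputee": (80, 70, 54, 4),
        "major_amputee": (6, 14, 7, 2),
    },
    "sensation": {
        "overall": (17, 220),
        "any_nonamputee": (13, 149),
        "any_amputee": (4, 71),
        "major_nonamputee": (16, 192),
        "major_amputee": (1, 28),
    },
}

#: Published model summaries. Keys: (outcome, prior_mode) -> factor ->
#: (beta_median, (beta_hdi_low, beta_hdi_high), odds_ratio, (or_hdi_low, or_hdi_high)).
#: Odds ratios are the exponentiated posterior beta medians; OR intervals are the
#: endpoint-exponentiated beta HDIs.
MODEL_SUMMARIES = {
    ("any", "uninformed"): {
        "perfusion": (0.688, (0.264, 1.152), 1.990, (1.302, 3.164)),
        "extent": (1.484, (0.617, 2.376), 4.411, (1.853, 10.762)),
        "depth": (0.665, (0.050, 1.418), 1.945, (1.051, 4.128)),
        "infection": (-0.112, (-0.483, 0.266), 0.894, (0.617, 1.305)),
        "sensation": (0.037, (-0.726, 1.077), 1.037, (0.484, 2.937)),
    },
    ("any", "informed"): {
        "perfusion": (0.703, (0.352, 1.116), 2.020, (1.422, 3.052)),
        "extent": (1.283, (0.562, 2.233), 3.609, (1.754, 9.326)),
        "depth": (0.656, (0.168, 1.302), 1.927, (1.183, 3.677)),
        "infection": (-0.021, (-0.439, 0.368), 0.979, (0.644, 1.446)),
        "sensation": (0.516, (-0.303, 1.223), 1.675, (0.738, 3.397)),
    },
    ("major", "uninformed"): {
        "perfusion": (0.471, (-0.017, 1.069), 1.601, (0.983, 2.913)),
        "extent": (0.985, (-0.079, 2.665), 2.678, (0.924, 14.364)),
        "depth": (0.932, (-0.088, 2.275), 2.540, (0.916, 9.726)),
        "infection": (0.155, (-0.296, 0.635), 1.167, (0.744, 1.888)),
        "sensation": (0.076, (-0.861, 1.782), 1.079, (0.423, 5.943)),
    },
    ("major", "informed"): {
        "perfusion": (0.586, (0.170, 1.070), 1.798, (1.185, 2.914)),
        "extent": (0.799, (0.061, 2.272), 2.222, (1.063, 9.702)),
        "depth": (0.694, (0.069, 1.893), 2.001, (1.071, 6.642)),
        "infection": (0.368, (-0.108, 0.757), 1.445, (0.898, 2.131)),
        "sensation": (0.553, (-0.404, 1.639), 1.738, (0.668, 5.149)),
    },
}

#: Posterior-median AUC and 95% HDI per model.
AUC_SUMMARIES = {
    ("any", "uninformed"): (0.793, (0.778, 0.801)),
    ("any", "informed"): (0.790, (0.774, 0.802)),
    ("major", "uninformed"): (0.765, (0.725, 0.779)),
    ("major", "informed"): (0.790, (0.774, 0.802)),
}

#: Informed-vs-uninformed comparison per outcome: (delta_auc, cohens_d).
MODEL_COMPARISONS = {"any": (0.003, 0.224), "major": (0.029, 2.217)}


def overall_stage_probs() -> dict[str, tuple[float, ...]]:
    """Marginal stage probabilities of the full cohort, per risk factor."""
    return {
        factor: tuple(c / COHORT_N for c in groups["overall"])
        for factor, groups in STAGE_COUNTS.items()
    }
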