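"""Published summary of the clinical calibration cohort.

The synthetic generator's defaults are calibrated to a retrospective
dual-tracer (FDG + CXCR4) PET cohort of 22 relapsed/refractory multiple
myeloma patients (24 therapy cycles).  These are the cohort-level lesion
counts and distribution summaries reported for that cohort; they are used
to sanity-check the partition arithmetic of the concordance adjudication
and the calibration of the generator, not as test oracles for any
computation on images.
"""

#: lesion category counts across the whole clinical cohort
LESION_COUNTS = {
    "total": 1352,
    "concordant": 520,
    "CXCR4_only": 661,
    "CXCR4_only_medullary": 420,
    "CXCR4_only_extramedullary": 241,
    "FDG_only": 171,
    "FDG_only_medullary": 60,
    "FDG_only_extramedullary": 111,
}

#: per-patient lesion count: median and (min, max)
LESIONS_PER_PATIENT = {"median": 64.5, "range": (20, 109)}

#: per-patient concordant-lesion fraction (as fractions, not %)
CONCORDANT_FRACTION = {"median": 0.400, "range": (0.056, 0.871)}

#: per-patient extramedullary lesion fraction
EXTRAMEDULLARY_FRACTION = {"median": 0.398, "range": (0.048, 0.775)}

#: cohort survival summary (days)
MEDIAN_OS_DAYS = 198.0

#: cohort size
N_PATIENTS = 22
N_CYCLES = 24
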