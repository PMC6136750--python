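"""Reference confusion-count fixtures for the performance-statistic checks.

Each row: (name, n_negative_total, n_positive_total, TP, TN, FP, FN,
expected {sen, spe, ppv, npv, acc, p_vus}), with None for cells that are
not computable.  VUS tallies are derived from the class totals:
VUS_pos = n_pos - TP - FN, VUS_neg = n_neg - TN - FP.
"""

# 23 in silico prediction rows; class totals 747 negatives / 414 positives.
INSILICO_N_NEG = 747
INSILICO_N_POS = 414

INSILICO_ROWS = [
    ("MutPred", 101, 496, 1, 17, dict(sen=0.244, spe=0.664, ppv=0.990, npv=0.967, acc=0.971, p_vus=0.470)),
    ("phyloP vertebrate", 75, 438, 6, 15, dict(sen=0.181, spe=0.586, ppv=0.926, npv=0.967, acc=0.961, p_vus=0.540)),
    ("MutationAssessor", 71, 315, 0, 9, dict(sen=0.171, spe=0.422, ppv=1.000, npv=0.972, acc=0.977, p_vus=0.660)),
    ("FATHMM", 99, 276, 2, 6, dict(sen=0.239, spe=0.369, ppv=0.980, npv=0.979, acc=0.979, p_vus=0.670)),
    ("AGVGD", 217, 0, 18, 0, dict(sen=0.524, spe=0.000, ppv=0.923, npv=None, acc=0.923, p_vus=0.798)),
    ("Polyphen2 HVAR", 0, 414, 0, 21, dict(sen=0.000, spe=0.554, ppv=None, npv=0.952, acc=0.952, p_vus=0.625)),
    ("SiPhy", 0, 277, 0, 5, dict(sen=0.000, spe=0.371, ppv=None, npv=0.982, acc=0.982, p_vus=0.757)),
    ("LRT", 0, 291, 0, 8, dict(sen=0.000, spe=0.390, ppv=None, npv=0.973, acc=0.973, p_vus=0.742)),
    ("GERP++", 0, 329, 0, 12, dict(sen=0.000, spe=0.440, ppv=None, npv=0.965, acc=0.965, p_vus=0.706)),
    ("Polyphen2 HDIV", 0, 404, 0, 26, dict(sen=0.000, spe=0.541, ppv=None, npv=0.940, acc=0.940, p_vus=0.630)),
    ("SIFT", 0, 315, 0, 12, dict(sen=0.000, spe=0.422, ppv=None, npv=0.963, acc=0.963, p_vus=0.718)),
    ("PROVEAN", 50, 102, 1, 2, dict(sen=0.121, spe=0.137, ppv=0.980, npv=0.981, acc=0.981, p_vus=0.866)),
    ("phastCons mammalian", 0, 361, 0, 14, dict(sen=0.000, spe=0.483, ppv=None, npv=0.963, acc=0.963, p_vus=0.677)),
    ("phastCons vertebrate", 0, 455, 0, 10, dict(sen=0.000, spe=0.609, ppv=None, npv=0.978, acc=0.978, p_vus=0.599)),
    ("phyloP mammalian", 0, 213, 0, 5, dict(sen=0.000, spe=0.285, ppv=None, npv=0.977, acc=0.977, p_vus=0.812)),
    ("Grantham", 0, 0, 0, 0, dict(sen=0.000, spe=0.000, ppv=None, npv=None, acc=None, p_vus=1.000)),
    ("IVP", 148, 489, 0, 4, dict(sen=0.357, spe=0.655, ppv=1.000, npv=0.992, acc=0.994, p_vus=0.448)),
    ("REVEL", 90, 475, 4, 20, dict(sen=0.217, spe=0.636, ppv=0.957, npv=0.960, acc=0.959, p_vus=0.493)),
    ("MetaSVM", 0, 518, 0, 16, dict(sen=0.000, spe=0.693, ppv=None, npv=0.970, acc=0.970, p_vus=0.540)),
    ("Eigen", 22, 497, 0, 4, dict(sen=0.053, spe=0.665, ppv=1.000, npv=0.992, acc=0.992, p_vus=0.550)),
    ("Eigen PC", 12, 506, 0, 5, dict(sen=0.029, spe=0.677, ppv=1.000, npv=0.990, acc=0.990, p_vus=0.550)),
    ("CADD", 61, 330, 17, 3, dict(sen=0.147, spe=0.442, ppv=0.782, npv=0.991, acc=0.951, p_vus=0.646)),
    ("MutationTaster", 0, 517, 0, 13, dict(sen=0.000, spe=0.692, ppv=None, npv=0.975, acc=0.975, p_vus=0.543)),
]

# 8 multifactorial rows: (name, n_neg, n_pos, TP, TN, FP, FN, expected)
MULTIFACTORIAL_ROWS = [
    ("all evidence / any", 686, 330, 263, 519, 2, 0, dict(sen=0.797, spe=0.757, ppv=0.992, npv=1.000, acc=0.997, p_vus=0.228)),
    ("all evidence / LR<0.1 or >10", 372, 226, 210, 358, 2, 0, dict(sen=0.929, spe=0.962, ppv=0.991, npv=1.000, acc=0.996, p_vus=0.047)),
    ("all evidence / LR<0.01 or >100", 223, 74, 74, 223, 0, 0, dict(sen=1.000, spe=1.000, ppv=1.000, npv=1.000, acc=1.000, p_vus=0.000)),
    ("all evidence / LR<0.001 or >1000", 155, 23, 23, 155, 0, 0, dict(sen=1.000, spe=1.000, ppv=1.000, npv=1.000, acc=1.000, p_vus=0.000)),
    ("auto evidence / any", 618, 255, 95, 287, 2, 0, dict(sen=0.373, spe=0.464, ppv=0.979, npv=1.000, acc=0.995, p_vus=0.560)),
    ("auto evidence / LR<0.1 or >10", 225, 35, 31, 212, 2, 0, dict(sen=0.886, spe=0.942, ppv=0.939, npv=1.000, acc=0.992, p_vus=0.058)),
    ("auto evidence / LR<0.01 or >100", 174, 8, 8, 174, 0, 0, dict(sen=1.000, spe=1.000, ppv=1.000, npv=1.000, acc=1.000, p_vus=0.000)),
    ("auto evidence / LR<0.001 or >1000", 107, 0, 0, 107, 0, 0, dict(sen=None, spe=1.000, ppv=None, npv=1.000, acc=1.000, p_vus=0.000)),
]


def confusion_from_row(n_neg, n_pos, tp, tn, fp, fn):
    """Rebuild a ConfusionSummary, deriving the VUS split from class totals."""
    from bayesvar import ConfusionSummary

    return ConfusionSummary(
        TP=tp, TN=tn, FP=fp, FN=fn,
        VUS_pos=n_pos - tp - fn, VUS_neg=n_neg - tn - fp,
    )


def insilico_cases():
    for name, tp, tn, fp, fn, expected in INSILICO_ROWS:
        yield name, confusion_from_row(INSILICO_N_NEG, INSILICO_N_POS, tp, tn, fp, fn), expected


def multifactorial_cases():
    for name, n_neg, n_pos, tp, tn, fp, fn, expected in MULTIFACTORIAL_ROWS:
        yield name, confusion_from_row(n_neg, n_pos, tp, tn, fp, fn), expected
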