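"""Published reference dose-response parameters for the two-channel panel.

The originating assay-validation study fitted 4PL dose-response curves to
continuous-luminescence and direct-cell-count rate data for a panel of
small-cell lung cancer lines against kinase inhibitors and cytotoxics, and
published the fitted parameters (Hill coefficient, maximal response, EC50 in
molar, residual sum of squares).  Two lines — H1048 and H841 — were measured
on *both* channels from the same wells across six drugs, giving the 12
matched pairs used for the cross-channel Wilcoxon and mechanism-concordance
analyses.  The table is bundled here verbatim so those paired analyses run
without the raw plate data.
"""

from __future__ import annotations

import io

import pandas as pd

from .plate_io import validate_result_table

__all__ = ["load_reference_fits", "load_paired_reference_fits", "PAIRED_CELL_LINES"]

#: Cell lines measured on both the luminescence and direct-count channels.
PAIRED_CELL_LINES = ("H1048", "H841")

_REFERENCE_FITS_CSV = """\
cell_line,drug,data_type,hill_coef,max_resp,ec50_M,residuals
DMS114,Barasertib,Lum,8.754,-0.079,7.86e-09,9.812
DMS114,AMG-900,Lum,0.544,-0.234,1.69e-09,9.254
DMS114,TAK-901,Lum,4.181,-0.074,1.6e-08,4.990
DMS114,YM-155,Lum,9.527,-0.034,6.91e-08,13.579
DMS114,SCH-1473759,Lum,0.485,-0.131,5.74e-09,7.134
DMS114,Etoposide,Lum,14.618,-0.049,4.83e-07,16.446
DMS114,SNS-314,Lum,0.143,-0.564,2.88e-09,11.205
DMS454,Barasertib,Lum,0.192,-5.000,733,17.492
DMS454,AMG-900,Lum,2.816,-1.841,1.172,3.981
DMS454,TAK-901,Lum,0.187,-4.834,6.25e-04,61.902
DMS454,YM-155,Lum,14.273,-0.480,7.6e-08,19.917
DMS454,SCH-1473759,Lum,0.490,-5.000,3.81e-05,30.889
DMS454,Etoposide,Lum,10.439,-1.163,2.99e-06,305.999
DMS454,SNS-314,Lum,0.535,-0.511,1.44e-08,70.104
CORL279,Barasertib,Lum,0.482,0.143,5.13e-09,2.275
CORL279,AMG-900,Lum,0.047,-0.414,5.44e-09,4.109
CORL279,TAK-901,Lum,1.027,-0.114,4.42e-08,1.755
CORL279,YM-155,Lum,0.572,-0.172,2.83e-09,8.129
CORL279,SCH-1473759,Lum,0.313,-0.391,1.55e-09,4.560
CORL279,Etoposide,Lum,0.088,-0.967,5.5e-09,19.581
CORL279,SNS-314,Lum,0.000,-1.608,65.5,5.726
H1930,Barasertib,Lum,0.396,0.134,2.57e-08,4.891
H1930,AMG-900,Lum,0.950,0.500,7e-10,6.743
H1930,TAK-901,Lum,1.350,0.080,9.01e-08,6.072
H1930,YM-155,Lum,1.528,-0.253,2e-09,48.869
H1930,SCH-1473759,Lum,0.318,-0.550,5.59e-07,3.666
H1930,Etoposide,Lum,0.126,-1.089,3.37e-09,7.514
H526,Barasertib,Lum,2.818,-1.859,1.159,3.562
H526,AMG-900,Lum,2.821,-1.887,1.111,44.650
H526,TAK-901,Lum,14.720,0.402,2.39e-06,23.102
H526,YM-155,Lum,0.299,0.084,5.12e-08,9.928
H526,SCH-1473759,Lum,13.750,0.101,2.47e-06,24.866
H526,SNS-314,Lum,0.000,-0.103,2.18e-09,101.411
H1048,Barasertib,Lum,3.431,-0.209,1.44e-08,10.332
H1048,hygromycin_b,Lum,0.577,0.635,1.1e-04,13.097
H1048,Trametinib,Lum,1.054,0.238,1.37e-07,12.033
H1048,SCH-1473759,Lum,1.333,-0.219,2.86e-09,17.029
H1048,YM-155,Lum,0.995,-0.186,2.74e-09,4.925
H1048,TAK-901,Lum,2.508,-0.209,1.45e-08,17.176
H1048,SNS-314,Lum,2.507,-0.069,4.95e-09,14.051
H841,Barasertib,Lum,0.520,-0.427,3.96e-09,44.403
H841,hygromycin_b,Lum,2.817,-1.851,1.16,17.366
H841,Trametinib,Lum,0.799,-0.281,2.1e-08,17.401
H841,SCH-1473759,Lum,3.777,-0.363,4.17e-09,59.188
H841,YM-155,Lum,0.999,-0.794,9.79e-09,86.686
H841,TAK-901,Lum,2.342,-0.380,1.45e-08,13.628
H841,SNS-314,Lum,2.465,-0.377,8.42e-09,14.323
DMS53,Barasertib,Lum,2.817,-1.855,1.151,395.696
DMS53,hygromycin_b,Lum,2.717,0.857,5.28e-08,117.582
DMS53,Trametinib,Lum,1.032,-0.659,1.38e-08,85.699
DMS53,SCH-1473759,Lum,0.201,-4.430,2.17e-03,47.346
DMS53,YM-155,Lum,0.483,-0.696,2.89e-09,46.906
DMS53,TAK-901,Lum,0.203,-5.000,4.42e-03,45.003
DMS53,SNS-314,Lum,0.781,-5.000,1.54e-04,138.641
DMS53,Vemurafenib,Lum,0.230,-5.000,5.49e-03,43.273
H1048,SNS-314,Direct,0.339,-1.673,1.31e-08,3.812
H1048,Trametinib,Direct,1.009,0.137,2.29e-08,9.877
H1048,SCH-1473759,Direct,0.601,-1.588,3.32e-09,2.783
H1048,YM-155,Direct,0.730,-1.703,3.01e-10,22.686
H1048,TAK-901,Direct,1.692,-1.294,2.11e-08,1.317
H1048,Barasertib,Direct,0.322,-2.742,6.29e-07,6.424
H841,SNS-314,Direct,0.550,-0.351,1.12e-09,1.208
H841,Trametinib,Direct,2.111,0.588,5.46e-07,0.124
H841,SCH-1473759,Direct,1.312,-0.072,5.33e-09,3.166
H841,YM-155,Direct,1.216,-0.818,2.61e-10,4.012
H841,TAK-901,Direct,2.328,-0.633,6.33e-08,0.634
H841,Barasertib,Direct,0.442,-5.000,1.55e-05,0.544
"""


def load_reference_fits() -> pd.DataFrame:
    """The full published parameter table (one row per cell line / drug /
    data channel) as a validated result table."""
    return validate_result_table(pd.read_csv(io.StringIO(_REFERENCE_FITS_CSV), float_precision="round_trip"))


def load_paired_reference_fits() -> pd.DataFrame:
    """The 24-row subset covering the two cell lines measured on both
    channels, restricted to drugs present in both — the 12 matched pairs."""
    table = load_reference_fits()
    table = table[table["cell_line"].isin(PAIRED_CELL_LINES)]
    both = (
        table.groupby(["cell_line", "drug"])["data_type"]
        .nunique()
        .pipe(lambda s: s[s == 2])
        .index
    )
    mask = table.set_index(["cell_line", "drug"]).index.isin(both)
    return table[mask].reset_index(drop=True)
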