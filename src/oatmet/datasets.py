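"""Reference data from a published UK winter oat multi-environment trial.

Four commercially grown winter oat varieties (Balado, Gerald, Mascani,
Tardis) were trialled at nine UK sites over four harvest years
(2011-2014), giving 22 site-by-year "environments".  The per-environment
and per-variety summary tables of that trial are embedded here verbatim
as small CSV blocks: they are the only published record of the data
(plot-level values were never deposited) and serve as fixtures for
trait-formula checks, trait-weather correlation analysis and
balanced-design consistency checks.

Conventions
-----------
* Missing values are encoded as ``na`` in the CSV blocks and surface as
  ``NaN``.  Environment 8 was spring sown (February), so its
  December-April rainfall window does not exist; environments 15 and 18
  have no hectoliter-weight record.
* Dates are ISO-8601.  Yields are t/ha at 15% moisture, grain number in
  thousand grains per m2, hectoliter weight in kg/hL, TGW (thousand
  grain weight) in g, grain dimensions in mm, composition traits in %.
* Variety-level tables carry both the mean and the environmental
  sensitivity slope b from the trial's modified joint-regression
  analysis, plus the published standard errors and F-test probabilities
  at trait level.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = [
    "SPRING_SOWN_ENVIRONMENTS",
    "HECTOLITER_MISSING_ENVIRONMENTS",
    "load_trial_environments",
    "load_environment_quality_means",
    "load_environment_dimension_means",
    "load_environment_means",
    "load_variety_quality_summary",
    "load_variety_dimension_summary",
    "load_variety_summary",
    "load_trait_level_errors",
]

#: Environment sown in spring rather than the previous autumn.
SPRING_SOWN_ENVIRONMENTS = frozenset({8})

#: Environments with no hectoliter-weight record.
HECTOLITER_MISSING_ENVIRONMENTS = frozenset({15, 18})

# Field sites, sowing/harvest dates and seasonal weather aggregates.
# rain_dec_apr: cumulative rainfall (mm) December-April before harvest;
# rain_jun_jul: cumulative June+July rainfall (mm) of the harvest year;
# temp_mar / temp_jul: mean monthly air temperature (degC).
_ENVIRONMENTS_CSV = """\
environment,site,latitude,longitude,sowing_date,harvest_date,rain_dec_apr,rain_jun_jul,temp_mar,temp_jul
1,Gogerddan,52.43,-4.02,2011-09-28,2012-08-09,387,273,8.0,13.9
2,Gogerddan,52.43,-4.02,2012-10-23,2013-08-18,426,91,2.9,16.6
3,Gogerddan,52.43,-4.02,2013-09-25,2014-07-24,574,96,6.8,15.7
4,Lydbury,52.45,-2.94,2011-09-30,2012-08-22,270,211,7.9,14.3
5,Lydbury,52.45,-2.94,2013-10-08,2014-08-20,316,84,6.4,16.2
6,Bidney,52.20,-2.87,2010-10-15,2011-08-17,145,105,6.1,14.4
7,Rosemaund,52.08,-2.39,2011-10-06,2012-09-05,325,249,8.1,14.8
8,Rosemaund,51.97,-2.62,2013-02-06,2013-09-03,na,56,2.4,17.9
9,Rosemaund,51.98,-2.60,2013-09-30,2014-07-31,555,88,6.9,16.9
10,ADAS Rosemaund,52.09,-2.39,2010-09-28,2011-08-13,149,93,6.6,15.0
11,ADAS Rosemaund,52.09,-2.39,2011-09-27,2012-09-06,325,249,8.1,14.8
12,ORC Elm Farm,52.36,1.35,2010-10-19,2011-08-03,131,126,6.4,15.3
13,ORC Elm Farm,52.36,1.35,2011-10-12,2012-08-22,275,168,8.1,16.0
14,ORC Elm Farm,52.36,1.35,2012-10-16,2013-08-24,292,35,2.7,17.6
15,Glenrothes,56.19,-3.11,2011-09-28,2012-08-24,205,260,7.0,12.5
16,Glenrothes,56.19,-3.11,2012-10-02,2013-08-14,317,90,1.4,15.4
17,Glenrothes,56.19,-3.11,2013-09-26,2014-08-04,360,105,5.2,14.8
18,Devon,50.27,-3.76,2011-10-03,2012-08-28,420,275,9.0,15.0
19,Devon,50.27,-3.76,2012-10-20,2013-08-13,442,43,5.3,17.2
20,Devon,50.27,-3.76,2013-10-07,2014-07-31,565,120,8.3,17.2
21,Essex,51.58,0.41,2011-10-06,2012-08-16,218,193,8.5,16.0
22,Essex,51.58,0.41,2013-10-05,2014-07-22,232,94,8.0,17.7
"""

# Per-environment means (over the four varieties) of yield and physical
# grain quality.
_ENV_QUALITY_CSV = """\
environment,yield,grain_number,groat_content,hullability,hectoliter_weight,tgw
1,6.03,16.03,68.65,90.07,43.14,37.65
2,8.31,19.90,73.45,77.46,50.17,41.89
3,9.31,24.83,68.88,83.44,50.26,37.92
4,8.08,18.20,75.49,93.60,46.01,44.96
5,7.92,16.56,75.48,91.36,53.66,48.18
6,10.02,22.06,75.23,88.32,55.35,45.27
7,6.77,16.78,73.42,98.50,44.47,40.41
8,4.96,12.38,75.73,93.03,50.89,41.40
9,7.18,17.41,74.13,86.82,49.24,41.74
10,10.19,24.16,74.68,71.34,52.94,42.00
11,4.84,10.88,75.88,99.58,51.12,44.55
12,7.98,18.97,73.97,91.34,59.57,42.55
13,7.26,17.85,73.55,93.06,49.65,40.66
14,9.74,23.24,72.91,76.37,51.88,42.04
15,7.61,17.35,73.08,95.55,na,44.60
16,8.79,22.02,73.22,84.52,52.13,40.23
17,9.69,22.45,72.99,80.28,53.17,43.25
18,6.83,17.86,69.72,97.52,na,38.40
19,10.49,26.62,72.55,75.76,51.76,39.66
20,9.94,22.94,72.73,83.17,50.99,43.62
21,8.20,20.62,74.36,97.23,42.64,39.47
22,9.43,26.84,70.56,83.90,49.14,35.52
"""

# Per-environment means of grain dimensions and composition.
_ENV_DIMENSION_CSV = """\
environment,width,length,roundness,oil,protein,beta_glucan
1,3.10,10.83,0.287,7.82,8.42,3.72
2,3.13,12.79,0.245,7.03,10.40,4.61
3,3.06,10.74,0.286,7.79,7.77,4.70
4,3.30,11.04,0.300,7.33,10.18,3.82
5,3.34,10.69,0.312,7.21,9.54,4.44
6,3.25,11.79,0.276,7.37,9.59,4.35
7,3.19,10.42,0.306,7.21,9.65,3.61
8,3.08,12.58,0.244,6.48,12.11,4.88
9,3.11,11.09,0.281,7.24,8.36,4.60
10,3.16,12.31,0.258,7.66,11.85,4.11
11,3.27,11.10,0.295,6.59,11.10,3.98
12,3.19,10.67,0.300,7.27,10.83,4.19
13,3.18,12.24,0.262,7.00,10.88,3.97
14,3.13,12.18,0.258,7.34,9.70,4.29
15,3.31,10.86,0.306,7.83,9.06,3.35
16,3.08,11.92,0.259,6.99,9.97,4.63
17,3.20,10.79,0.297,7.69,8.42,4.27
18,3.14,10.26,0.307,7.74,8.95,3.16
19,3.08,12.55,0.246,7.59,8.79,4.21
20,3.21,10.98,0.293,7.19,7.88,4.43
21,3.11,10.52,0.297,7.23,10.88,3.74
22,2.94,10.67,0.276,7.70,12.33,4.61
"""

# Variety means (V_i) and joint-regression sensitivities (b_i), tidy
# long format: one row per (variety, trait).
_VARIETY_QUALITY_CSV = """\
variety,trait,mean,sensitivity
Balado,yield,7.98,1.151
Gerald,yield,8.24,0.982
Mascani,yield,8.18,1.020
Tardis,yield,8.25,0.844
Balado,grain_number,19.31,1.218
Gerald,grain_number,22.16,1.078
Mascani,grain_number,18.05,0.912
Tardis,grain_number,19.74,0.785
Balado,groat_content,70.82,1.744
Gerald,groat_content,72.81,1.096
Mascani,groat_content,76.78,0.525
Tardis,groat_content,72.23,0.590
Balado,hullability,83.64,1.522
Gerald,hullability,87.75,1.052
Mascani,hullability,98.54,0.129
Tardis,hullability,81.38,1.290
Balado,hectoliter_weight,48.09,1.085
Gerald,hectoliter_weight,52.16,0.998
Mascani,hectoliter_weight,52.22,0.926
Tardis,hectoliter_weight,49.16,0.990
Balado,tgw,41.81,1.381
Gerald,tgw,37.44,0.988
Mascani,tgw,45.39,0.799
Tardis,tgw,41.90,0.808
"""

_VARIETY_DIMENSION_CSV = """\
variety,trait,mean,sensitivity
Balado,width,3.16,1.316
Gerald,width,3.09,0.952
Mascani,width,3.23,0.817
Tardis,width,3.17,0.901
Balado,length,11.62,1.030
Gerald,length,10.53,0.866
Mascani,length,11.23,1.066
Tardis,length,11.89,1.038
Balado,roundness,0.273,0.986
Gerald,roundness,0.294,0.890
Mascani,roundness,0.290,1.142
Tardis,roundness,0.268,0.982
Balado,oil,7.53,1.450
Gerald,oil,7.36,0.786
Mascani,oil,6.70,0.906
Tardis,oil,7.72,0.817
Balado,protein,9.92,1.056
Gerald,protein,9.54,0.956
Mascani,protein,9.76,1.011
Tardis,protein,10.13,0.977
Balado,beta_glucan,4.76,1.101
Gerald,beta_glucan,3.57,0.986
Mascani,beta_glucan,4.26,1.068
Tardis,beta_glucan,4.07,0.843
"""

# Trait-level standard errors and F-test probabilities published with
# the variety summaries. prob values "<0.001" are stored as 0.001 with
# the censoring recorded in prob_*_censored.
_TRAIT_ERRORS_CSV = """\
trait,se_mean,se_sensitivity,prob_mean,prob_mean_censored,prob_sensitivity,prob_sensitivity_censored
yield,0.167,0.1046,0.625,False,0.270,False
grain_number,0.420,0.1022,0.001,True,0.028,False
groat_content,0.227,0.1108,0.001,True,0.001,True
hullability,0.761,0.0957,0.001,True,0.001,True
hectoliter_weight,0.358,0.0907,0.001,True,0.691,False
tgw,0.341,0.1184,0.001,True,0.005,False
width,0.011,0.113,0.001,True,0.025,False
length,0.050,0.063,0.001,True,0.119,False
roundness,0.0014,0.0666,0.001,True,0.074,False
oil,0.047,0.127,0.001,True,0.004,False
protein,0.09,0.065,0.001,True,0.729,False
beta_glucan,0.043,0.097,0.001,True,0.263,False
"""


def _read(csv_text: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(csv_text), na_values=["na"], **kwargs)


def load_trial_environments() -> pd.DataFrame:
    """Site, date and seasonal-weather metadata for the 22 environments.

    Returns a frame indexed by ``environment`` (1..22) with site
    coordinates, ISO sowing/harvest dates, windowed rainfall sums (mm),
    March/July mean temperatures (degC) and a ``spring_sown`` flag.
    """
    df = _read(
        _ENVIRONMENTS_CSV, parse_dates=["sowing_date", "harvest_date"]
    ).set_index("environment")
    df["spring_sown"] = df.index.isin(SPRING_SOWN_ENVIRONMENTS)
    return df


def load_environment_quality_means() -> pd.DataFrame:
    """Per-environment means of yield and physical grain quality."""
    return _read(_ENV_QUALITY_CSV).set_index("environment")


def load_environment_dimension_means() -> pd.DataFrame:
    """Per-environment means of grain dimensions and composition."""
    return _read(_ENV_DIMENSION_CSV).set_index("environment")


def load_environment_means() -> pd.DataFrame:
    """All twelve per-environment trait means joined into one frame."""
    return load_environment_quality_means().join(load_environment_dimension_means())


def load_variety_quality_summary() -> pd.DataFrame:
    """Variety means and sensitivity slopes for the six quality traits."""
    return _read(_VARIETY_QUALITY_CSV)


def load_variety_dimension_summary() -> pd.DataFrame:
    """Variety means and sensitivity slopes for dimensions/composition."""
    return _read(_VARIETY_DIMENSION_CSV)


def load_variety_summary() -> pd.DataFrame:
    """All variety-level means and slopes, tidy (variety, trait) rows."""
    return pd.concat(
        [load_variety_quality_summary(), load_variety_dimension_summary()],
        ignore_index=True,
    )


def load_trait_level_errors() -> pd.DataFrame:
    """Published trait-level standard errors and F-test probabilities."""
    return _read(_TRAIT_ERRORS_CSV).set_index("trait")
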