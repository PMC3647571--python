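# Default coefficient set: system-GMM time-path equations for five
# cardiovascular risk factors, estimated on Swedish National Diabetes
# Register patients newly diagnosed with type 2 diabetes in 2001-2004.
#
# Significance markers: "1%", "5%", "10%" (the usual ***/**/* ladder),
# "ns" (estimated but not significant at 10%; value retained if printed),
# "na" (covariate not included in the equation).
# The systolic BP equation is estimated and stored on a /10 scale
# (public_scale: 10 means public mmHg = 10 x equation units).
name: ndr_table2
equations:
  hba1c:
    units: "% (DCCT)"
    public_scale: 1.0
    constant: {value: 3.055, sig: "1%"}
    lag: {value: 0.526, sig: "1%"}
    covariates:
      ln_duration: {value: 0.182, sig: "1%"}
      year1: {value: -0.144, sig: "10%"}
      age_at_diagnosis: {value: -0.008, sig: "1%"}
      female: {value: -0.034, sig: "10%"}
      smoking: {value: 0.192, sig: ns, endogenous: true}
      bmi: {value: 0.015, sig: "1%"}
      bmi_squared: {sig: ns}
    meta: {n_patients: 4450, person_years: 20699, hansen_p: 0.053, ar1_p: "<0.001", ar2_p: 0.356}
  sbp:
    units: "mmHg"
    public_scale: 10.0
    constant: {value: 5.546, sig: "5%"}
    lag: {value: 0.466, sig: "5%"}
    covariates:
      ln_duration: {value: -0.050, sig: ns}
      year1: {sig: na}
      age_at_diagnosis: {value: 0.021, sig: "10%"}
      female: {value: -0.064, sig: "5%"}
      smoking: {value: 0.094, sig: "1%"}
      bmi: {value: 0.017, sig: "1%"}
      bmi_squared: {sig: ns}
    meta: {n_patients: 4158, person_years: 20144, hansen_p: 0.588, ar1_p: "<0.001", ar2_p: 0.095}
  tchdl:
    units: "ratio"
    public_scale: 1.0
    constant: {value: 1.647, sig: "5%"}
    lag: {value: 0.541, sig: "1%"}
    covariates:
      ln_duration: {value: 0.099, sig: ns}
      year1: {sig: na}
      age_at_diagnosis: {value: -0.009, sig: "5%"}
      female: {value: -0.144, sig: "1%"}
      smoking: {value: 0.071, sig: ns}
      bmi: {value: 0.021, sig: "1%"}
      bmi_squared: {sig: ns}
    meta: {n_patients: 2274, person_years: 10157, hansen_p: 0.654, ar1_p: "<0.001", ar2_p: 0.219}
  ldl:
    units: "mmol/L"
    public_scale: 1.0
    constant: {value: 1.938, sig: "1%"}
    lag: {value: 0.352, sig: "1%"}
    covariates:
      ln_duration: {value: -0.059, sig: "1%"}
      year1: {sig: na}
      age_at_diagnosis: {value: -0.007, sig: "1%"}
      female: {value: 0.060, sig: "1%"}
      smoking: {value: 0.091, sig: ns}
      bmi: {value: 0.018, sig: "5%"}
      bmi_squared: {value: -0.0003, sig: "5%"}
    meta: {n_patients: 2068, person_years: 9536, hansen_p: 0.461, ar1_p: "<0.001", ar2_p: 0.310}
  bmi:
    units: "kg/m^2"
    public_scale: 1.0
    constant: {value: 6.832, sig: "10%"}
    lag: {value: 0.811, sig: "1%"}
    covariates:
      ln_duration: {value: 0.106, sig: "1%"}
      year1: {sig: na}
      age_at_diagnosis: {value: -0.022, sig: "5%"}
      female: {value: 0.134, sig: ns}
      smoking: {value: -0.370, sig: "1%"}
      bmi: {sig: na}
      bmi_squared: {sig: na}
    meta: {n_patients: 4284, person_years: 25447, hansen_p: 0.126, ar1_p: "<0.001", ar2_p: 0.078}
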