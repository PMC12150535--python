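# Default latent trajectory profiles for the synthetic cohort generator.
#
# Case groups (SIDD, SIRD, MOD, MARD): `intercept` is the latent mean 20 years
# before the classification exam; `slope_pre` / `slope_post` are per-year
# slopes before / after the classification time point (piecewise linear with
# the breakpoint at classification).
# Controls: `intercept` is the latent mean at the baseline exam and the single
# calendar-time slope is carried in `slope_pre` (slope_post is ignored).
#
# Units: fpg mg/dL, fasting_insulin mIE/L, bmi kg/m^2, whr dimensionless,
# sbp/dbp mmHg. Values are illustrative defaults chosen so group orderings
# mimic the qualitative epidemiology (highest glucose in the insulin-deficient
# group, highest insulin/insulin-resistance in the insulin-resistant group,
# highest BMI in the obesity-related group, flattest trends in controls); they
# are not estimates of any real cohort's parameters.
profiles:
  SIDD:
    fpg: {intercept: 110.0, slope_pre: 2.5, slope_post: 0.1}
    fasting_insulin: {intercept: 12.0, slope_pre: -0.05, slope_post: 0.5}
    bmi: {intercept: 25.5, slope_pre: 0.10, slope_post: 0.10}
    whr: {intercept: 0.91, slope_pre: 0.002, slope_post: 0.002}
    sbp: {intercept: 126.0, slope_pre: 1.2, slope_post: 0.4}
    dbp: {intercept: 77.0, slope_pre: 0.5, slope_post: 0.3}
  SIRD:
    fpg: {intercept: 100.0, slope_pre: 1.5, slope_post: 1.2}
    fasting_insulin: {intercept: 18.0, slope_pre: 0.6, slope_post: -0.4}
    bmi: {intercept: 27.0, slope_pre: 0.15, slope_post: 0.05}
    whr: {intercept: 0.90, slope_pre: 0.003, slope_post: 0.001}
    sbp: {intercept: 124.0, slope_pre: 1.0, slope_post: -0.1}
    dbp: {intercept: 76.0, slope_pre: 0.5, slope_post: 0.0}
  MOD:
    fpg: {intercept: 98.0, slope_pre: 1.5, slope_post: 1.0}
    fasting_insulin: {intercept: 12.0, slope_pre: 0.4, slope_post: -0.3}
    bmi: {intercept: 28.0, slope_pre: 0.20, slope_post: -0.10}
    whr: {intercept: 0.87, slope_pre: 0.004, slope_post: 0.000}
    sbp: {intercept: 123.0, slope_pre: 0.9, slope_post: -0.3}
    dbp: {intercept: 75.0, slope_pre: 0.5, slope_post: -0.2}
  MARD:
    fpg: {intercept: 95.0, slope_pre: 1.5, slope_post: 0.8}
    fasting_insulin: {intercept: 12.0, slope_pre: 0.05, slope_post: 0.3}
    bmi: {intercept: 25.0, slope_pre: 0.10, slope_post: 0.05}
    whr: {intercept: 0.88, slope_pre: 0.002, slope_post: 0.002}
    sbp: {intercept: 122.0, slope_pre: 0.9, slope_post: -0.1}
    dbp: {intercept: 75.0, slope_pre: 0.4, slope_post: -0.1}
  control:
    fpg: {intercept: 82.0, slope_pre: 0.2, slope_post: 0.2}
    fasting_insulin: {intercept: 12.5, slope_pre: -0.025, slope_post: -0.025}
    bmi: {intercept: 24.5, slope_pre: 0.05, slope_post: 0.05}
    whr: {intercept: 0.83, slope_pre: 0.002, slope_post: 0.002}
    sbp: {intercept: 118.0, slope_pre: 0.5, slope_post: 0.5}
    dbp: {intercept: 72.0, slope_pre: 0.25, slope_post: 0.25}
random_intercept_sd:
  fpg: 4.0
  fasting_insulin: 3.0
  bmi: 2.5
  whr: 0.05
  sbp: 10.0
  dbp: 6.0
residual_sd:
  fpg: 5.0
  fasting_insulin: 3.0
  bmi: 1.0
  whr: 0.02
  sbp: 8.0
  dbp: 5.0
# 2-h post-load glucose is generated as factor * fasting glucose + noise;
# cases show an exaggerated post-load response, controls dispose of the load.
glucose_2h:
  factor: {SIDD: 1.55, SIRD: 1.45, MOD: 1.45, MARD: 1.40, control: 0.95}
  sd: 12.0
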