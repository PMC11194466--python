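# Default model parameters: annual transition probabilities, risks, mortalities,
# 2022-USD costs by payer block, and health-state utilities for the
# postpolypectomy colorectal-cancer prevention model.
#
# Conventions: entries in the transitions / risks / mortality / compliance
# blocks are PERCENT (converted to probabilities at load time); costs are USD
# per event or per year; utilities are raw QALY weights. `family` selects the
# probabilistic-sensitivity-analysis sampling distribution (beta for
# probabilities/utilities, gamma for costs, fixed = excluded from sampling).

transitions:
  sp_to_lra_berberine:        {base: 18.15, low: 16.34, high: 19.97, family: beta}
  sp_to_hra_berberine:        {base: 1.51,  low: 1.36,  high: 1.66,  family: beta}
  lra_to_hra_berberine:       {base: 8.90,  low: 8.34,  high: 9.45,  family: beta}
  hra_to_crc_berberine:       {base: 5.00,  low: 4.50,  high: 5.50,  family: beta}
  sp_to_lra_placebo:          {base: 23.19, low: 20.87, high: 25.51, family: beta}
  sp_to_hra_placebo:          {base: 3.05,  low: 2.74,  high: 3.35,  family: beta}
  lra_to_hra_placebo:         {base: 8.90,  low: 8.34,  high: 9.45,  family: beta}
  hra_to_crc_placebo:         {base: 5.00,  low: 4.50,  high: 5.50,  family: beta}
  local_to_regional:          {base: 56.00, low: 50.40, high: 61.60, family: beta}
  regional_to_distant:        {base: 63.00, low: 56.70, high: 69.30, family: beta}
  present_local:              {base: 22.00, low: 19.80, high: 24.20, family: beta}
  present_regional:           {base: 40.00, low: 36.00, high: 44.00, family: beta}
  present_distant:            {base: 85.00, low: 76.50, high: 93.50, family: beta}
  lra_removal:                {base: 58.00, low: 55.00, high: 62.00, family: beta}
  hra_removal:                {base: 92.00, low: 88.00, high: 95.00, family: beta}
  colonoscopy_sensitivity_crc: {base: 94.70, low: 90.40, high: 97.20, family: beta}

compliance:
  compliance_colonoscopy:     {base: 60.00, low: 30.00, high: 100.00, family: beta}
  compliance_berberine:       {base: 80.00, low: 30.00, high: 100.00, family: beta}

risks:
  perforation_risk:           {base: 0.04, low: 0.02, high: 0.05, family: beta}
  bleeding_risk:              {base: 0.08, low: 0.05, high: 0.14, family: beta}

mortality:
  mort_crc_local:             {base: 3.27,  low: 2.73,  high: 3.90,  family: beta}
  mort_crc_regional:          {base: 8.22,  low: 7.52,  high: 8.98,  family: beta}
  mort_crc_distant:           {base: 46.93, low: 45.49, high: 48.39, family: beta}
  mort_perforation:           {base: 5.82,  low: 5.238, high: 6.40,  family: beta}
  mort_bleeding:              {base: 6.00,  low: 1.00,  high: 16.00, family: beta}
  mort_cancer_treatment:      {base: 2.00,  low: 1.80,  high: 2.20,  family: beta}

costs_shared:
  cost_berberine_annual:      {base: 124.00, low: 99.20, high: 148.80, family: gamma}

costs_commercial:
  cost_colonoscopy:           {base: 1385.55,  low: 1108.44,  high: 1662.66,  family: gamma}
  cost_colonoscopy_polypectomy: {base: 1853.59, low: 1482.88, high: 2224.31,  family: gamma}
  cost_perforation:           {base: 24834.22, low: 19867.37, high: 29801.06, family: gamma}
  cost_bleeding:              {base: 9164.61,  low: 7331.69,  high: 10997.53, family: gamma}
  cost_crc_local_initial:     {base: 43093.75, low: 34475.00, high: 51712.50, family: gamma}
  cost_crc_local_continuing:  {base: 3428.45,  low: 2742.76,  high: 4114.14,  family: gamma}
  cost_crc_local_death:       {base: 77251.68, low: 61801.35, high: 92702.02, family: gamma}
  cost_crc_regional_initial:  {base: 72510.85, low: 58008.68, high: 87013.02, family: gamma}
  cost_crc_regional_continuing: {base: 4568.95, low: 3655.16, high: 5482.74,  family: gamma}
  cost_crc_regional_death:    {base: 81170.25, low: 64936.20, high: 97404.30, family: gamma}
  cost_crc_distant_initial:   {base: 94686.62, low: 75749.30, high: 113623.95, family: gamma}
  cost_crc_distant_death:     {base: 108937.00, low: 87149.60, high: 130724.40, family: gamma}

costs_medicare:
  cost_colonoscopy:           {base: 786.27,   low: 629.01,   high: 943.52,   family: gamma}
  cost_colonoscopy_polypectomy: {base: 1011.58, low: 809.26,  high: 1213.90,  family: gamma}
  cost_perforation:           {base: 18396.58, low: 14717.26, high: 22075.89, family: gamma}
  cost_bleeding:              {base: 6788.38,  low: 5430.71,  high: 8146.06,  family: gamma}
  cost_crc_local_initial:     {base: 31921.08, low: 25536.86, high: 38305.29, family: gamma}
  cost_crc_local_continuing:  {base: 2539.98,  low: 2031.99,  high: 3047.98,  family: gamma}
  cost_crc_local_death:       {base: 57223.34, low: 45778.67, high: 68668.01, family: gamma}
  cost_crc_regional_initial:  {base: 53712.43, low: 42969.94, high: 64454.91, family: gamma}
  cost_crc_regional_continuing: {base: 3384.32, low: 2707.46, high: 64454.91, family: gamma}
  cost_crc_regional_death:    {base: 60125.68, low: 48100.54, high: 72150.81, family: gamma}
  cost_crc_distant_initial:   {base: 70138.11, low: 56110.49, high: 84165.73, family: gamma}
  cost_crc_distant_death:     {base: 80694.07, low: 64555.26, high: 96832.89, family: gamma}

utilities:
  utility_non_crc:            {base: 0.84,   low: 0.80,   high: 0.88,   family: beta}
  utility_crc_local:          {base: 0.74,   low: 0.69,   high: 0.78,   family: beta}
  utility_crc_regional:       {base: 0.67,   low: 0.62,   high: 0.72,   family: beta}
  utility_crc_distant:        {base: 0.25,   low: 0.20,   high: 0.31,   family: beta}
  disutility_colonoscopy:     {base: 0.0025, low: 0.0023, high: 0.0028, family: beta}

discount:
  discount_rate:              {base: 3.00, family: fixed}

# Two-year adenoma recurrence proportions from the randomized berberine trial
# (percent over two years); used only to cross-check the four derived annual
# recurrence rows above via the constant-rate conversion.
trial_two_year:
  lra_berberine: 33.0
  hra_berberine: 3.0
  lra_placebo: 41.0
  hra_placebo: 6.0
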