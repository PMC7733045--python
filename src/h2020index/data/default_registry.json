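{
  "_comment": "Default Health 2020 monitoring structure: 6 targets, 19 indicators, 16 quantitative. The indicator-to-target mapping is editable configuration, not code; this default is a synthetic reconstruction that preserves the framework's documented structure (qualitative indicators 11/18/19, 2015-only indicators 2/14, 2010-onward indicators 4/10, multi-target indicators 7/9/10/11, quantitative targets 1-5).",
  "targets": [
    {"target_id": 1, "name": "Reduce premature mortality", "is_quantitative": true},
    {"target_id": 2, "name": "Increase life expectancy", "is_quantitative": true},
    {"target_id": 3, "name": "Reduce inequities in health", "is_quantitative": true},
    {"target_id": 4, "name": "Enhance well-being", "is_quantitative": true},
    {"target_id": 5, "name": "Universal coverage and the right to health", "is_quantitative": true},
    {"target_id": 6, "name": "National targets set by Member States", "is_quantitative": false}
  ],
  "indicators": [
    {"indicator_id": 1, "name": "Premature mortality from major NCDs", "is_quantitative": true, "direction": "lower_better", "target_ids": [1], "available_reference_years": [2005, 2010, 2015]},
    {"indicator_id": 2, "name": "Tobacco use prevalence", "is_quantitative": true, "direction": "lower_better", "target_ids": [1], "available_reference_years": [2015]},
    {"indicator_id": 3, "name": "Alcohol consumption per capita", "is_quantitative": true, "direction": "lower_better", "target_ids": [1], "available_reference_years": [2005, 2010, 2015]},
    {"indicator_id": 4, "name": "Overweight prevalence", "is_quantitative": true, "direction": "lower_better", "target_ids": [1], "available_reference_years": [2010, 2015]},
    {"indicator_id": 5, "name": "Measles vaccination coverage", "is_quantitative": true, "direction": "higher_better", "target_ids": [1], "available_reference_years": [2005, 2010, 2015]},
    {"indicator_id": 6, "name": "Mortality from external causes", "is_quantitative": true, "direction": "lower_better", "target_ids": [1], "available_reference_years": [2005, 2010, 2015]},
    {"indicator_id": 7, "name": "Life expectancy at birth", "is_quantitative": true, "direction": "higher_better", "target_ids": [1, 2], "available_reference_years": [2005, 2010, 2015]},
    {"indicator_id": 8, "name": "Infant mortality rate", "is_quantitative": true, "direction": "lower_better", "target_ids": [3], "available_reference_years": [2005, 2010, 2015]},
    {"indicator_id": 9, "name": "Primary school enrolment", "is_quantitative": true, "direction": "higher_better", "target_ids": [3, 4], "available_reference_years": [2005, 2010, 2015]},
    {"indicator_id": 10, "name": "Unemployment rate", "is_quantitative": true, "direction": "lower_better", "target_ids": [3, 4], "available_reference_years": [2010, 2015]},
    {"indicator_id": 11, "name": "GINI coefficient (income distribution)", "is_quantitative": false, "direction": "lower_better", "target_ids": [3, 4], "available_reference_years": [2005, 2010, 2015]},
    {"indicator_id": 12, "name": "Life satisfaction", "is_quantitative": true, "direction": "higher_better", "target_ids": [4], "available_reference_years": [2005, 2010, 2015]},
    {"indicator_id": 13, "name": "Out-of-pocket health expenditure share", "is_quantitative": true, "direction": "lower_better", "target_ids": [5], "available_reference_years": [2005, 2010, 2015]},
    {"indicator_id": 14, "name": "Perceived social support", "is_quantitative": true, "direction": "higher_better", "target_ids": [4], "available_reference_years": [2015]},
    {"indicator_id": 15, "name": "Total health expenditure (% of GDP)", "is_quantitative": true, "direction": "higher_better", "target_ids": [5], "available_reference_years": [2005, 2010, 2015]},
    {"indicator_id": 16, "name": "Health insurance / service coverage", "is_quantitative": true, "direction": "higher_better", "target_ids": [5], "available_reference_years": [2005, 2010, 2015]},
    {"indicator_id": 17, "name": "Unmet need for medical care", "is_quantitative": true, "direction": "lower_better", "target_ids": [5], "available_reference_years": [2005, 2010, 2015]},
    {"indicator_id": 18, "name": "National health policy aligned with the framework", "is_quantitative": false, "direction": "higher_better", "target_ids": [6], "available_reference_years": [2015]},
    {"indicator_id": 19, "name": "Process for setting national targets established", "is_quantitative": false, "direction": "higher_better", "target_ids": [6], "available_reference_years": [2015]}
  ]
}
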