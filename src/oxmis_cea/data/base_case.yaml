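# Base-case inputs for the suicide-risk-assessment cost-effectiveness model.
# Flat namespace matching oxmis_cea.parameters.ParameterSet.
# Probabilities are annual; costs in GBP; utilities on the 0 (death) - 1 scale.

p_high_oxmis: 0.25          # 1 - specificity (0.75) of the structured tool
p_high_clinical: 0.5        # HRM assignment under unstructured judgment
p_suicide_high: 0.017       # annual suicide risk, tool's high-risk stratum
p_suicide_overall: 0.008    # 12-month suicide incidence in SMI
hrm_risk_reduction: 0.10    # relative risk reduction from high-risk management

cost_oxmis: 57              # administering the structured assessment
cost_clinical_assessment: 253   # unstructured psychosocial assessment
cost_hrm: 1615              # high-risk management package
cost_lrm: 0                 # low-risk management adds no cost
cost_suicide: 260           # direct emergency/health cost of a suicide

utility_smi: 0.77           # annual utility living with SMI
utility_decrement_hrm: 0.05 # disutility of high-risk management
utility_death: 0

time_horizon_years: 1
wtp_threshold: 20000        # GBP per QALY, for NMB and the CEAC
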