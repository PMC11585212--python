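# Default rule set: Norwegian national recommendations for empirical
# antibiotic therapy in suspected community-acquired pneumonia, keyed on
# CRB-65 severity band, penicillin allergy, eGFR band and ICU status.
# Pattern semantics: a regimen is adherent under a pattern when every
# administered agent can be assigned to a component (strict matching) and
# every component receives at least `min` (default 1) and at most `max`
# (default unlimited) agents.
name: norwegian_cap_2020
strict: true
empirical_rules:
  - rule_id: low_band_no_allergy
    condition: {crb65_band: low, penicillin_allergy: false}
    description: >-
      Mild/moderate CAP (CRB-65 0-2), no penicillin allergy: benzylpenicillin,
      phenoxymethylpenicillin, ampicillin, amoxicillin, or any combination.
    patterns:
      - components:
          - codes: [benzylpenicillin, phenoxymethylpenicillin, ampicillin, amoxicillin]
  - rule_id: low_band_allergy
    condition: {crb65_band: low, penicillin_allergy: true}
    description: >-
      Mild/moderate CAP with penicillin allergy: any single macrolide.
    patterns:
      - components:
          - {agent_class: macrolide, max: 1}
  - rule_id: high_band_allergy
    condition: {crb65_band: high, penicillin_allergy: true}
    description: >-
      Severe CAP (CRB-65 >= 3) with penicillin allergy: clindamycin plus a
      quinolone.
    patterns:
      - components:
          - codes: [clindamycin]
          - agent_class: quinolone
  - rule_id: high_band_icu
    condition: {crb65_band: high, penicillin_allergy: false, icu: true}
    description: >-
      Severe CAP admitted to ICU: cefotaxime, ceftriaxone or
      piperacillin/tazobactam, each combined with a quinolone.
    patterns:
      - components:
          - codes: [cefotaxime, ceftriaxone, piperacillin_tazobactam]
            max: 1
          - agent_class: quinolone
  - rule_id: high_band_low_egfr
    condition: {crb65_band: high, penicillin_allergy: false, egfr_band: lt30}
    description: >-
      Severe CAP with eGFR < 30 mL/min/1.73m2 (aminoglycoside avoided):
      cefotaxime or ceftriaxone.
    patterns:
      - components:
          - codes: [cefotaxime, ceftriaxone]
            max: 1
  - rule_id: high_band_standard
    condition: {crb65_band: high, penicillin_allergy: false}
    description: >-
      Severe CAP, preserved kidney function, ward care: benzylpenicillin or
      ampicillin combined with an aminoglycoside (gentamicin or tobramycin).
    patterns:
      - components:
          - codes: [benzylpenicillin, ampicillin]
            max: 1
          - codes: [gentamicin, tobramycin]
            max: 1
duration_rules:
  - {crb65_band: low, recommended_days: 5, margin_h: 24}
  - {crb65_band: high, recommended_days: 7, margin_h: 24}
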