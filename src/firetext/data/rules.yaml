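# Default context-categorization rules for firearm keyword hits.
#
# Seven mutually exclusive note categories.  A single match is labeled by the
# first rule in match_rule_order whose cues fire against the match's context
# window (name_contains_term uses proper-name detection and template_shot the
# template_phrases list instead of cues); a note takes the highest-precedence
# label among its matches.  Cue matching is lowercase phrase containment.
version: builtin-v1

precedence:
  - exposure
  - assessment
  - guidance_education
  - treatment_care
  - template_shot
  - name_contains_term
  - other

match_rule_order:
  - name_contains_term
  - template_shot
  - other
  - treatment_care
  - guidance_education
  - assessment
  - exposure

cues:
  exposure:
    - hears gunshots
    - gunshot wound
    - suffered a gsw
    - gsw
    - robbed at gunpoint
    - gunpoint
    - gun in his mouth
    - gun in her mouth
    - history of gunshot
    - gunshot
    - was shot
    - shot at him
    - shot at her
  assessment:
    - no access to firearms
    - access to firearms
    - no guns
    - do you have any guns
    - any guns in the home?
    - talks or writes about death
    - talking about guns
    - guns in the home. locked
    - denies
  guidance_education:
    - remove guns
    - make sure any guns
    - gun safety
    - blasting caps
    - lock and key
    - education done
    - education provided
  treatment_care:
    - shooting pain
    - hepatitis
    - dmpa
    - cortisone
    - flu shot
    - immunization
    - vaccine
    - birth control
    - tetanus
  other:
    - nailgun
    - snap shot
  template_shot: []
  name_contains_term: []

# Pre-set EHR boilerplate (SmartPhrases) containing firearm keywords.
template_phrases:
  - "[shot for birth control: care instructions.]"
  - "[flu shot: care instructions.]"

# Context cues marking "shot" as an injectable medication, not a firearm.
injectable_cues:
  - immunization
  - vaccine
  - hepatitis
  - dmpa
  - cortisone
  - birth control
  - flu
  - tetanus
  - injection
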