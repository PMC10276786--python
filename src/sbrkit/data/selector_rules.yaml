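# Milestone-driven sBR methodology rules, reconstructed from the textually
# stated recommendations of the framework (the full decision algorithm is
# published only as a figure and is not reproduced here). Organizations can
# edit this file and load it via selector.load_rules(path).
#
# Matching: first rule whose `when` clause matches the project state wins.
# A missing key in `when` matches any value.
rules:
  - when: {milestone: ftih}
    recommend: [context_table]
    category: descriptive
    rationale: >-
      At first-time-in-human, key benefits and risks are often not yet
      definable; a modified FDA-style context table collates the treatment
      space and the emerging evidence package.
  - when: {milestone: phase2b}
    recommend: [value_tree, weighted_value_tree]
    category: descriptive
    rationale: >-
      By the Phase IIb investment decision, key benefits and risks are
      usually identified: represent them as a value tree and introduce
      weighting (ordinal ranking; anchor-100 Delphi for products heading
      toward fully quantitative analysis).
  - when: {milestone: phase3, data_maturity: pivotal}
    recommend: [effects_table]
    category: semi_quantitative
    rationale: >-
      With pivotal trials underway and sufficient data, fill out an
      effects table of key benefits and risks with observed or estimated
      frequencies and their uncertainties.
  - when: {milestone: phase3}
    recommend: [weighted_value_tree]
    category: descriptive
    rationale: >-
      Where data from earlier phases are limited (accelerated programs,
      rare disease or underserved indications), weighted value trees are
      the alternative methodology, with the effects table completed later
      during Phase III as data allow.
  - when: {milestone: submission, br_complexity: complex_or_borderline}
    recommend: [nnt_nnh, mcda]
    category: fully_quantitative
    rationale: >-
      Fully quantitative options — NNT/NNH when a single key benefit is
      compared like-with-like against a single key risk, MCDA when the
      criteria are multiple and disparate — are recommended for products
      with more complex or borderline benefit-risk scenarios.
  - when: {milestone: submission, data_maturity: minimal}
    recommend: [weighted_value_tree]
    category: descriptive
    rationale: >-
      With extremely limited or difficult-to-interpret data, a descriptive
      position can still be appropriate at submission; a weighted value
      tree keeps the prioritization of benefits and risks explicit.
  - when: {milestone: submission}
    recommend: [effects_table, forest_plot]
    category: semi_quantitative
    rationale: >-
      A semi-quantitative Core Company BR position — an effects table
      and/or a risk-ratio forest plot — is the base case at regulatory
      submission for reasonably positive, straightforward profiles.
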