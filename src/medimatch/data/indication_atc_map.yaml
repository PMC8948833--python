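# ATC prefixes defining the drug classes of the three frequent disorders
# used in the three-way concordance analysis.  The prefix sets are this
# package's editable approximation of "drugs prescribed for <disorder>";
# metabolite lists are filled from the platform drug-category column plus
# the per-indication overrides below.
hypertension:
  atc_prefixes: [C02, C03, C07, C08, C09]
  metabolite_overrides: []
dyslipidemia:
  atc_prefixes: [C10]
  metabolite_overrides: []
diabetes:
  atc_prefixes: [A10]
  metabolite_overrides: []
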