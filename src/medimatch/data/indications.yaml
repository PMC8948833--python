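# Phrase -> indication lexicon for free-text answers that name a disease
# but no drug ("tablets for blood pressure" -> unspecified hypertension).
# Editable: add local phrasings as needed; matching is on normalized text.
blood pressure: hypertension
hypertension: hypertension
hypertensive: hypertension
cholesterol: dyslipidemia
dyslipidemia: dyslipidemia
lipid: dyslipidemia
diabetes: diabetes
diabetic: diabetes
blood sugar: diabetes
sugar: diabetes
thyroid: thyroid
heart: cardiac
asthma: asthma
allergy: allergy
allergies: allergy
anemia: anemia
depression: depression
anxiety: anxiety
pain: pain
headache: pain
migraine: migraine
stomach: gastric
gastric: gastric
reflux: gastric
vitamins: supplement
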