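# Default map from IrAE category to the questionnaire items whose
# moderate/severe report counts as "related symptoms" when linking an
# alert questionnaire to that event.  Categories mapped to an empty
# list (laboratory-detected toxicities, connective-tissue disease and
# the catch-all) have no questionnaire-visible symptom signature under
# the default instrument.  Edit or replace this file to change linkage.
skin_toxicity: [rash]
colitis_digestive: [diarrhea, nausea_vomiting, decreased_appetite]
hepatitis: [fatigue, nausea_vomiting]
thyroiditis: [fatigue, headache, nausea_vomiting]
hypophysitis: [fatigue, headache, nausea_vomiting]
rheumatological: [general_pain]
myositis: [general_pain]
ophthalmological: [blurred_vision]
dry_syndrome: [blurred_vision]
interstitial_pneumonitis: [shortness_of_breath, fever]
nephritis: []
hyperlipasemia: []
mixed_connective_tissue: []
other: []
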