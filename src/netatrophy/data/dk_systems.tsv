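name	yeo7	von_economo
lh_bankssts	dorsal_attention	association_2
lh_caudalanteriorcingulate	ventral_attention	limbic
lh_caudalmiddlefrontal	dorsal_attention	association_1
lh_cuneus	visual	secondary_sensory
lh_entorhinal	limbic	limbic
lh_fusiform	visual	association_2
lh_inferiorparietal	default	association_2
lh_inferiortemporal	default	association_2
lh_isthmuscingulate	default	limbic
lh_lateraloccipital	visual	secondary_sensory
lh_lateralorbitofrontal	limbic	association_1
lh_lingual	visual	secondary_sensory
lh_medialorbitofrontal	limbic	association_1
lh_middletemporal	default	association_2
lh_parahippocampal	limbic	limbic
lh_paracentral	somatomotor	primary_motor
lh_parsopercularis	ventral_attention	association_1
lh_parsorbitalis	frontoparietal	association_1
lh_parstriangularis	frontoparietal	association_1
lh_pericalcarine	visual	primary_sensory
lh_postcentral	somatomotor	primary_sensory
lh_posteriorcingulate	default	limbic
lh_precentral	somatomotor	primary_motor
lh_precuneus	default	association_2
lh_rostralanteriorcingulate	default	limbic
lh_rostralmiddlefrontal	frontoparietal	association_1
lh_superiorfrontal	default	association_1
lh_superiorparietal	dorsal_attention	association_2
lh_superiortemporal	somatomotor	association_2
lh_supramarginal	ventral_attention	association_2
lh_frontalpole	default	association_1
lh_temporalpole	limbic	limbic
lh_transversetemporal	somatomotor	primary_sensory
lh_insula	ventral_attention	insular
rh_bankssts	dorsal_attention	association_2
rh_caudalanteriorcingulate	ventral_attention	limbic
rh_caudalmiddlefrontal	dorsal_attention	association_1
rh_cuneus	visual	secondary_sensory
rh_entorhinal	limbic	limbic
rh_fusiform	visual	association_2
rh_inferiorparietal	default	association_2
rh_inferiortemporal	default	association_2
rh_isthmuscingulate	default	limbic
rh_lateraloccipital	visual	secondary_sensory
rh_lateralorbitofrontal	limbic	association_1
rh_lingual	visual	secondary_sensory
rh_medialorbitofrontal	limbic	association_1
rh_middletemporal	default	association_2
rh_parahippocampal	limbic	limbic
rh_paracentral	somatomotor	primary_motor
rh_parsopercularis	ventral_attention	association_1
rh_parsorbitalis	frontoparietal	association_1
rh_parstriangularis	frontoparietal	association_1
rh_pericalcarine	visual	primary_sensory
rh_postcentral	somatomotor	primary_sensory
rh_posteriorcingulate	default	limbic
rh_precentral	somatomotor	primary_motor
rh_precuneus	default	association_2
rh_rostralanteriorcingulate	default	limbic
rh_rostralmiddlefrontal	frontoparietal	association_1
rh_superiorfrontal	default	association_1
rh_superiorparietal	dorsal_attention	association_2
rh_superiortemporal	somatomotor	association_2
rh_supramarginal	ventral_attention	association_2
rh_frontalpole	default	association_1
rh_temporalpole	limbic	limbic
rh_transversetemporal	somatomotor	primary_sensory
rh_insula	ventral_attention	insular
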