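lh_bankssts	cerebrum
lh_caudalanteriorcingulate	cerebrum
lh_caudalmiddlefrontal	cerebrum
lh_cuneus	cerebrum
lh_entorhinal	cerebrum
lh_fusiform	cerebrum
lh_inferiorparietal	cerebrum
lh_inferiortemporal	cerebrum
lh_isthmuscingulate	cerebrum
lh_lateraloccipital	cerebrum
lh_lateralorbitofrontal	cerebrum
lh_lingual	cerebrum
lh_medialorbitofrontal	cerebrum
lh_middletemporal	cerebrum
lh_parahippocampal	cerebrum
lh_paracentral	cerebrum
lh_parsopercularis	cerebrum
lh_parsorbitalis	cerebrum
lh_parstriangularis	cerebrum
lh_pericalcarine	cerebrum
lh_postcentral	cerebrum
lh_posteriorcingulate	cerebrum
lh_precentral	cerebrum
lh_precuneus	cerebrum
lh_rostralanteriorcingulate	cerebrum
lh_rostralmiddlefrontal	cerebrum
lh_superiorfrontal	cerebrum
lh_superiorparietal	cerebrum
lh_superiortemporal	cerebrum
lh_supramarginal	cerebrum
lh_frontalpole	cerebrum
lh_temporalpole	cerebrum
lh_transversetemporal	cerebrum
lh_insula	cerebrum
rh_bankssts	cerebrum
rh_caudalanteriorcingulate	cerebrum
rh_caudalmiddlefrontal	cerebrum
rh_cuneus	cerebrum
rh_entorhinal	cerebrum
rh_fusiform	cerebrum
rh_inferiorparietal	cerebrum
rh_inferiortemporal	cerebrum
rh_isthmuscingulate	cerebrum
rh_lateraloccipital	cerebrum
rh_lateralorbitofrontal	cerebrum
rh_lingual	cerebrum
rh_medialorbitofrontal	cerebrum
rh_middletemporal	cerebrum
rh_parahippocampal	cerebrum
rh_paracentral	cerebrum
rh_parsopercularis	cerebrum
rh_parsorbitalis	cerebrum
rh_parstriangularis	cerebrum
rh_pericalcarine	cerebrum
rh_postcentral	cerebrum
rh_posteriorcingulate	cerebrum
rh_precentral	cerebrum
rh_precuneus	cerebrum
rh_rostralanteriorcingulate	cerebrum
rh_rostralmiddlefrontal	cerebrum
rh_superiorfrontal	cerebrum
rh_superiorparietal	cerebrum
rh_superiortemporal	cerebrum
rh_supramarginal	cerebrum
rh_frontalpole	cerebrum
rh_temporalpole	cerebrum
rh_transversetemporal	cerebrum
rh_insula	cerebrum
lh_thalamus	cerebrum
lh_caudate	cerebrum
lh_putamen	cerebrum
lh_pallidum	cerebrum
lh_hippocampus	cerebrum
lh_amygdala	cerebrum
lh_accumbens	cerebrum
rh_thalamus	cerebrum
rh_caudate	cerebrum
rh_putamen	cerebrum
rh_pallidum	cerebrum
rh_hippocampus	cerebrum
rh_amygdala	cerebrum
rh_accumbens	cerebrum
lh_cerebellum	cerebellum
rh_cerebellum	cerebellum
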