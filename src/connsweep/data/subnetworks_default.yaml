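# Default subnetwork memberships for the four resting-state systems analysed by
# the pipeline.  The published analysis names the systems but not their node
# lists; these defaults are reconstructions assembled from the node-level
# driver reports (every driver named there is a member of the respective
# default) plus conventional resting-state definitions.  They are fully
# overridable: pass your own YAML/JSON of the same shape to load_subnetworks.
aal:
  sensorimotor:
    - Precentral_L
    - Precentral_R
    - Postcentral_L
    - Postcentral_R
    - Supp_Motor_Area_L
    - Supp_Motor_Area_R
    - Paracentral_Lobule_L
    - Paracentral_Lobule_R
    - Rolandic_Oper_L
    - Rolandic_Oper_R
    - Frontal_Sup_L
    - Frontal_Sup_R
    - Frontal_Mid_L
    - Frontal_Mid_R
  default_mode:
    - Frontal_Sup_L
    - Frontal_Sup_R
    - Frontal_Sup_Medial_L
    - Frontal_Sup_Medial_R
    - Frontal_Med_Orb_L
    - Frontal_Med_Orb_R
    - Frontal_Mid_L
    - Frontal_Mid_R
    - Frontal_Inf_Oper_L
    - Frontal_Inf_Oper_R
    - Frontal_Inf_Tri_L
    - Frontal_Inf_Tri_R
    - Frontal_Inf_Orb_L
    - Frontal_Inf_Orb_R
    - Cingulum_Ant_L
    - Cingulum_Ant_R
    - Cingulum_Mid_L
    - Cingulum_Mid_R
    - Cingulum_Post_L
    - Cingulum_Post_R
    - Hippocampus_L
    - Hippocampus_R
    - ParaHippocampal_L
    - ParaHippocampal_R
    - Occipital_Mid_L
    - Occipital_Mid_R
    - Angular_L
    - Angular_R
    - Precuneus_L
    - Precuneus_R
    - Temporal_Mid_L
    - Temporal_Mid_R
    - Thalamus_L
    - Thalamus_R
  visual:
    - Calcarine_L
    - Calcarine_R
    - Cuneus_L
    - Cuneus_R
    - Lingual_L
    - Lingual_R
    - Occipital_Sup_L
    - Occipital_Sup_R
    - Occipital_Mid_L
    - Occipital_Mid_R
    - Occipital_Inf_L
    - Occipital_Inf_R
    - Fusiform_L
    - Fusiform_R
  auditory:
    - Heschl_L
    - Heschl_R
    - Temporal_Sup_L
    - Temporal_Sup_R
    - Rolandic_Oper_L
    - Rolandic_Oper_R
desikan_killiany:
  sensorimotor:
    - lh_precentral
    - rh_precentral
    - lh_postcentral
    - rh_postcentral
    - lh_paracentral
    - rh_paracentral
    - lh_superiorfrontal
    - rh_superiorfrontal
    - lh_supramarginal
    - rh_supramarginal
  default_mode:
    - lh_rostralanteriorcingulate
    - rh_rostralanteriorcingulate
    - lh_caudalanteriorcingulate
    - rh_caudalanteriorcingulate
    - lh_posteriorcingulate
    - rh_posteriorcingulate
    - lh_isthmuscingulate
    - rh_isthmuscingulate
    - lh_precuneus
    - rh_precuneus
    - lh_inferiorparietal
    - rh_inferiorparietal
    - lh_parahippocampal
    - rh_parahippocampal
    - lh_medialorbitofrontal
    - rh_medialorbitofrontal
    - lh_lateralorbitofrontal
    - rh_lateralorbitofrontal
    - lh_caudalmiddlefrontal
    - rh_caudalmiddlefrontal
    - lh_rostralmiddlefrontal
    - rh_rostralmiddlefrontal
    - lh_parstriangularis
    - rh_parstriangularis
    - lh_hippocampus
    - rh_hippocampus
    - lh_thalamus
    - rh_thalamus
  visual:
    - lh_pericalcarine
    - rh_pericalcarine
    - lh_cuneus
    - rh_cuneus
    - lh_lingual
    - rh_lingual
    - lh_lateraloccipital
    - rh_lateraloccipital
    - lh_fusiform
    - rh_fusiform
  auditory:
    - lh_transversetemporal
    - rh_transversetemporal
    - lh_superiortemporal
    - rh_superiortemporal
    - lh_bankssts
    - rh_bankssts
toy20:
  sensorimotor: [smn_1, smn_2, smn_3, smn_4, smn_5]
  default_mode: [dmn_1, dmn_2, dmn_3, dmn_4, dmn_5]
  visual: [vis_1, vis_2, vis_3, vis_4, vis_5]
  auditory: [aud_1, aud_2, aud_3, aud_4, aud_5]
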