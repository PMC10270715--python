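Precentral_L	cerebrum
Precentral_R	cerebrum
Frontal_Sup_L	cerebrum
Frontal_Sup_R	cerebrum
Frontal_Sup_Orb_L	cerebrum
Frontal_Sup_Orb_R	cerebrum
Frontal_Mid_L	cerebrum
Frontal_Mid_R	cerebrum
Frontal_Mid_Orb_L	cerebrum
Frontal_Mid_Orb_R	cerebrum
Frontal_Inf_Oper_L	cerebrum
Frontal_Inf_Oper_R	cerebrum
Frontal_Inf_Tri_L	cerebrum
Frontal_Inf_Tri_R	cerebrum
Frontal_Inf_Orb_L	cerebrum
Frontal_Inf_Orb_R	cerebrum
Rolandic_Oper_L	cerebrum
Rolandic_Oper_R	cerebrum
Supp_Motor_Area_L	cerebrum
Supp_Motor_Area_R	cerebrum
Olfactory_L	cerebrum
Olfactory_R	cerebrum
Frontal_Sup_Medial_L	cerebrum
Frontal_Sup_Medial_R	cerebrum
Frontal_Med_Orb_L	cerebrum
Frontal_Med_Orb_R	cerebrum
Rectus_L	cerebrum
Rectus_R	cerebrum
Insula_L	cerebrum
Insula_R	cerebrum
Cingulum_Ant_L	cerebrum
Cingulum_Ant_R	cerebrum
Cingulum_Mid_L	cerebrum
Cingulum_Mid_R	cerebrum
Cingulum_Post_L	cerebrum
Cingulum_Post_R	cerebrum
Hippocampus_L	cerebrum
Hippocampus_R	cerebrum
ParaHippocampal_L	cerebrum
ParaHippocampal_R	cerebrum
Amygdala_L	cerebrum
Amygdala_R	cerebrum
Calcarine_L	cerebrum
Calcarine_R	cerebrum
Cuneus_L	cerebrum
Cuneus_R	cerebrum
Lingual_L	cerebrum
Lingual_R	cerebrum
Occipital_Sup_L	cerebrum
Occipital_Sup_R	cerebrum
Occipital_Mid_L	cerebrum
Occipital_Mid_R	cerebrum
Occipital_Inf_L	cerebrum
Occipital_Inf_R	cerebrum
Fusiform_L	cerebrum
Fusiform_R	cerebrum
Postcentral_L	cerebrum
Postcentral_R	cerebrum
Parietal_Sup_L	cerebrum
Parietal_Sup_R	cerebrum
Parietal_Inf_L	cerebrum
Parietal_Inf_R	cerebrum
SupraMarginal_L	cerebrum
SupraMarginal_R	cerebrum
Angular_L	cerebrum
Angular_R	cerebrum
Precuneus_L	cerebrum
Precuneus_R	cerebrum
Paracentral_Lobule_L	cerebrum
Paracentral_Lobule_R	cerebrum
Caudate_L	cerebrum
Caudate_R	cerebrum
Putamen_L	cerebrum
Putamen_R	cerebrum
Pallidum_L	cerebrum
Pallidum_R	cerebrum
Thalamus_L	cerebrum
Thalamus_R	cerebrum
Heschl_L	cerebrum
Heschl_R	cerebrum
Temporal_Sup_L	cerebrum
Temporal_Sup_R	cerebrum
Temporal_Pole_Sup_L	cerebrum
Temporal_Pole_Sup_R	cerebrum
Temporal_Mid_L	cerebrum
Temporal_Mid_R	cerebrum
Temporal_Pole_Mid_L	cerebrum
Temporal_Pole_Mid_R	cerebrum
Temporal_Inf_L	cerebrum
Temporal_Inf_R	cerebrum
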