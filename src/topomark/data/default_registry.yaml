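# Default 42-region bilateral registry: Desikan-Killiany cortical parcellation
# (bilaterally averaged, 34 regions) plus eight standard subcortical structures.
# Users may substitute their own 42 labels via a file of the same shape.
regions:
  - {id: bankssts, lobe: temporal}
  - {id: caudal_anterior_cingulate, lobe: cingulate}
  - {id: caudal_middle_frontal, lobe: frontal}
  - {id: cuneus, lobe: occipital}
  - {id: entorhinal, lobe: temporal}
  - {id: frontal_pole, lobe: frontal}
  - {id: fusiform, lobe: temporal}
  - {id: inferior_parietal, lobe: parietal}
  - {id: inferior_temporal, lobe: temporal}
  - {id: insula, lobe: insula}
  - {id: isthmus_cingulate, lobe: cingulate}
  - {id: lateral_occipital, lobe: occipital}
  - {id: lateral_orbitofrontal, lobe: frontal}
  - {id: lingual, lobe: occipital}
  - {id: medial_orbitofrontal, lobe: frontal}
  - {id: middle_temporal, lobe: temporal}
  - {id: paracentral, lobe: frontal}
  - {id: parahippocampal, lobe: temporal}
  - {id: pars_opercularis, lobe: frontal}
  - {id: pars_orbitalis, lobe: frontal}
  - {id: pars_triangularis, lobe: frontal}
  - {id: pericalcarine, lobe: occipital}
  - {id: postcentral, lobe: parietal}
  - {id: posterior_cingulate, lobe: cingulate}
  - {id: precentral, lobe: frontal}
  - {id: precuneus, lobe: parietal}
  - {id: rostral_anterior_cingulate, lobe: cingulate}
  - {id: rostral_middle_frontal, lobe: frontal}
  - {id: superior_frontal, lobe: frontal}
  - {id: superior_parietal, lobe: parietal}
  - {id: superior_temporal, lobe: temporal}
  - {id: supramarginal, lobe: parietal}
  - {id: temporal_pole, lobe: temporal}
  - {id: transverse_temporal, lobe: temporal}
  - {id: hippocampus, lobe: temporal}
  - {id: amygdala, lobe: temporal}
  - {id: thalamus, lobe: subcortical}
  - {id: caudate, lobe: subcortical}
  - {id: putamen, lobe: subcortical}
  - {id: pallidum, lobe: subcortical}
  - {id: accumbens, lobe: subcortical}
  - {id: ventral_dc, lobe: subcortical}
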