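[
  {"id": 1, "acronym": "root", "name": "root", "parent_id": null},
  {"id": 2, "acronym": "grey", "name": "Basic cell groups and regions", "parent_id": 1},
  {"id": 3, "acronym": "Isocortex", "name": "Isocortex", "parent_id": 2},
  {"id": 4, "acronym": "SSp", "name": "Primary somatosensory area", "parent_id": 3},
  {"id": 5, "acronym": "TH", "name": "Thalamus", "parent_id": 2},
  {"id": 6, "acronym": "STR", "name": "Striatum", "parent_id": 2},
  {"id": 7, "acronym": "fiber tracts", "name": "fiber tracts", "parent_id": 1},
  {"id": 10, "acronym": "MOp", "name": "Primary motor area", "parent_id": 3},
  {"id": 11, "acronym": "MOs", "name": "Secondary motor area", "parent_id": 3},
  {"id": 12, "acronym": "SSp-ul", "name": "Primary somatosensory area, upper limb", "parent_id": 4},
  {"id": 13, "acronym": "SSp-ll", "name": "Primary somatosensory area, lower limb", "parent_id": 4},
  {"id": 14, "acronym": "SSp-un", "name": "Primary somatosensory area, unassigned", "parent_id": 4},
  {"id": 15, "acronym": "SSs", "name": "Supplemental somatosensory area", "parent_id": 3},
  {"id": 16, "acronym": "ACA", "name": "Anterior cingulate area", "parent_id": 3},
  {"id": 20, "acronym": "DORsm", "name": "Thalamus, sensory-motor cortex related", "parent_id": 5},
  {"id": 21, "acronym": "DORpm", "name": "Thalamus, polymodal association cortex related", "parent_id": 5},
  {"id": 22, "acronym": "STRd", "name": "Striatum dorsal region", "parent_id": 6},
  {"id": 30, "acronym": "cc", "name": "corpus callosum", "parent_id": 7}
]
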