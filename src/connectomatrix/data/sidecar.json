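{
 "publications": [
  {"identifier": "dejerine1895", "year": 1895, "species": "human", "method": "postmortem fixation; atlas"},
  {"identifier": "dejerine1901", "year": 1901, "species": "human", "method": "postmortem degeneration and lesion analysis; atlas"},
  {"identifier": "ludwig_klingler1956", "year": 1956, "species": "human", "method": "fiber microdissection (Klingler technique); atlas"},
  {"identifier": "makris1999", "year": 1999, "species": "human", "method": "MRI-based white matter parcellation; literature collation"},
  {"identifier": "makris2005", "year": 2005, "species": "human", "method": "DTI tractography"},
  {"identifier": "schmahmann2006", "year": 2006, "species": "macaque", "method": "autoradiographic tract tracing"}
 ],
 "pathways": [
  {"name": "SLF", "synonyms": ["superior longitudinal fascicle", "SLF II"], "class": "associational", "distance_category": "long_range"},
  {"name": "ILF", "synonyms": ["inferior longitudinal fascicle"], "class": "associational", "distance_category": "long_range"},
  {"name": "CB", "synonyms": ["cingulum bundle", "cingulum"], "class": "associational", "distance_category": "long_range"},
  {"name": "OFF", "synonyms": ["occipito-frontal fascicle", "OF fascicle", "occipitofrontal fascicle"], "class": "associational", "distance_category": "long_range"},
  {"name": "EmC", "synonyms": ["extreme capsule"], "class": "associational", "distance_category": "long_range"},
  {"name": "UF", "synonyms": ["uncinate fascicle", "uncinate fasciculus"], "class": "associational", "distance_category": "long_range"},
  {"name": "IC", "synonyms": ["internal capsule"], "class": "projection", "distance_category": "long_range"},
  {"name": "corticopontine", "synonyms": ["corticopontine pathway", "corticopontine tract"], "class": "projection", "distance_category": "long_range"},
  {"name": "corticostriatal", "synonyms": ["corticostriatal pathway"], "class": "projection", "distance_category": "long_range"},
  {"name": "amygdalofugal", "synonyms": ["amygdalofugal pathway", "ventral amygdalofugal pathway"], "class": "projection", "distance_category": "long_range"}
 ]
}
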