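# SYNTHETIC normative reference for the three raw-score tests.
#
# These are NOT published testing-manual norms (those are copyrighted and
# user-supplied); they are plausible single-stratum means/SDs used by the
# synthetic cohort generator and the test suite so the full raw -> z ->
# composite path can be exercised end to end. Replace with real manual
# norms (optionally stratified by age/education/sex) for real data.

jlo:
  - {age_min: 0, age_max: 200, mean: 24.0, sd: 4.0}
sdmt:
  - {age_min: 0, age_max: 200, mean: 45.0, sd: 10.0}
semantic_fluency:
  - {age_min: 0, age_max: 200, mean: 21.0, sd: 5.0}
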