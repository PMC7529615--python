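# SYNTHETIC class-conditional categorical parameters (lambda) for the cohort
# generator. These numbers are invented configuration, chosen to satisfy the
# qualitative contrasts the analysis assumes: the severe/CD class places more
# mass on abnormal levels (k > 1) for every feature except ulcers (f8), where
# the classes are nearly identical; the SNVA class favours the patchy level of
# f2. They are NOT estimates from any patient cohort.
version: 1
severity:
  # class 1 = mild Marsh (0/1/2), class 2 = severe Marsh (3a/3b/3c)
  class_probs: [0.38271604938271603, 0.6172839506172839]   # 31/81, 50/81
  lambda:
    class_1:
      f1: [0.45, 0.55]
      f2: [0.45, 0.15, 0.40]
      f3: [0.60, 0.40]
      f4: [0.55, 0.45]
      f5: [0.70, 0.30]
      f6: [0.90, 0.10]
      f7: [0.90, 0.10]
      f8: [0.970, 0.030]
      f9: [0.92, 0.08]
    class_2:
      f1: [0.12, 0.88]
      f2: [0.12, 0.10, 0.78]
      f3: [0.35, 0.65]
      f4: [0.30, 0.70]
      f5: [0.45, 0.55]
      f6: [0.75, 0.25]
      f7: [0.78, 0.22]
      f8: [0.965, 0.035]
      f9: [0.72, 0.28]
disease:
  # class 1 = SNVA, class 2 = CD
  class_probs: [0.2222222222222222, 0.7777777777777778]    # 18/81, 63/81
  lambda:
    class_1:
      f1: [0.40, 0.60]
      f2: [0.40, 0.35, 0.25]
      f3: [0.60, 0.40]
      f4: [0.55, 0.45]
      f5: [0.72, 0.28]
      f6: [0.88, 0.12]
      f7: [0.92, 0.08]
      f8: [0.970, 0.030]
      f9: [0.90, 0.10]
    class_2:
      f1: [0.18, 0.82]
      f2: [0.18, 0.07, 0.75]
      f3: [0.40, 0.60]
      f4: [0.35, 0.65]
      f5: [0.52, 0.48]
      f6: [0.78, 0.22]
      f7: [0.80, 0.20]
      f8: [0.963, 0.037]
      f9: [0.74, 0.26]
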