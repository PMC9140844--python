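# Default cohort calibration: per-group sizes, median (Q1-Q3) summaries and
# visual positivity rates of the three pathological groups of the study
# cohort (25 adenocarcinomas, 9 MIAs, 6 AIS; 40 nodules in total).
groups:
  - pathology: adenocarcinoma
    n: 25
    suv_median: 1.3
    suv_q1: 1.1
    suv_q3: 1.8
    hu_median: -437.0
    hu_q1: -529.0
    hu_q3: -377.0
    size_median: 19.0
    size_q1: 15.0
    size_q3: 23.0
    visual_rate: 0.88            # 22 / 25
  - pathology: MIA
    n: 9
    suv_median: 1.1
    suv_q1: 0.7
    suv_q3: 1.8
    hu_median: -411.0
    hu_q1: -631.0
    hu_q3: -313.0
    size_median: 13.3
    size_q1: 10.0
    size_q3: 20.0
    visual_rate: 0.4444444444444444   # 4 / 9
  - pathology: AIS
    n: 6
    suv_median: 0.6
    suv_q1: 0.5
    suv_q3: 0.9
    hu_median: -577.0
    hu_q1: -631.0
    hu_q3: -435.0
    size_median: 14.7
    size_q1: 12.0
    size_q3: 16.8
    visual_rate: 0.16666666666666666  # 1 / 6
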