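parameter,description,source
LVEF,left ventricular ejection fraction,Fig 9
LVFS,left ventricular fractional shortening,Fig 9
LVEDd,left ventricular end-diastolic dimension,Fig 9
LVEDs,left ventricular end-systolic dimension,Fig 9
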