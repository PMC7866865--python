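# Default activity catalog: the 19 ADLs and 15 fall types of the SisFall
# protocol, with nominal trial durations in seconds.  The four walking/jogging
# ADLs are recorded once for 100 s and later expanded into five 10-s windows;
# every other activity has five trials.
activities:
  D01: {label: ADL, name: "Walking slowly", nominal_duration: 100, long_record: true}
  D02: {label: ADL, name: "Walking quickly", nominal_duration: 100, long_record: true}
  D03: {label: ADL, name: "Jogging slowly", nominal_duration: 100, long_record: true}
  D04: {label: ADL, name: "Jogging quickly", nominal_duration: 100, long_record: true}
  D05: {label: ADL, name: "Walking upstairs and downstairs slowly", nominal_duration: 25, long_record: false}
  D06: {label: ADL, name: "Walking upstairs and downstairs quickly", nominal_duration: 25, long_record: false}
  D07: {label: ADL, name: "Slowly sit and get up in a half-height chair", nominal_duration: 12, long_record: false}
  D08: {label: ADL, name: "Quickly sit and get up in a half-height chair", nominal_duration: 12, long_record: false}
  D09: {label: ADL, name: "Slowly sit and get up in a low-height chair", nominal_duration: 12, long_record: false}
  D10: {label: ADL, name: "Quickly sit and get up in a low-height chair", nominal_duration: 12, long_record: false}
  D11: {label: ADL, name: "Sitting, trying to get up, and collapse into a chair", nominal_duration: 12, long_record: false}
  D12: {label: ADL, name: "Sitting, lying slowly, wait a moment, and sit again", nominal_duration: 12, long_record: false}
  D13: {label: ADL, name: "Sitting, lying quickly, wait a moment, and sit again", nominal_duration: 12, long_record: false}
  D14: {label: ADL, name: "Changing position while lying (back-lateral-back)", nominal_duration: 12, long_record: false}
  D15: {label: ADL, name: "Standing, slowly bending at knees, and getting up", nominal_duration: 12, long_record: false}
  D16: {label: ADL, name: "Standing, slowly bending without knees, and getting up", nominal_duration: 12, long_record: false}
  D17: {label: ADL, name: "Standing, get into and get out of a car", nominal_duration: 25, long_record: false}
  D18: {label: ADL, name: "Stumble while walking", nominal_duration: 12, long_record: false}
  D19: {label: ADL, name: "Gently jump without falling", nominal_duration: 12, long_record: false}
  F01: {label: FALL, name: "Fall forward while walking, caused by a slip", nominal_duration: 15, long_record: false}
  F02: {label: FALL, name: "Fall backward while walking, caused by a slip", nominal_duration: 15, long_record: false}
  F03: {label: FALL, name: "Lateral fall while walking, caused by a slip", nominal_duration: 15, long_record: false}
  F04: {label: FALL, name: "Fall forward while walking, caused by a trip", nominal_duration: 15, long_record: false}
  F05: {label: FALL, name: "Fall forward while jogging, caused by a trip", nominal_duration: 15, long_record: false}
  F06: {label: FALL, name: "Vertical fall while walking, caused by fainting", nominal_duration: 15, long_record: false}
  F07: {label: FALL, name: "Fall while walking with damping, caused by fainting", nominal_duration: 15, long_record: false}
  F08: {label: FALL, name: "Fall forward when trying to get up", nominal_duration: 15, long_record: false}
  F09: {label: FALL, name: "Lateral fall when trying to get up", nominal_duration: 15, long_record: false}
  F10: {label: FALL, name: "Fall forward when trying to sit down", nominal_duration: 15, long_record: false}
  F11: {label: FALL, name: "Fall backward when trying to sit down", nominal_duration: 15, long_record: false}
  F12: {label: FALL, name: "Lateral fall when trying to sit down", nominal_duration: 15, long_record: false}
  F13: {label: FALL, name: "Fall forward while sitting, caused by fainting", nominal_duration: 15, long_record: false}
  F14: {label: FALL, name: "Fall backward while sitting, caused by fainting", nominal_duration: 15, long_record: false}
  F15: {label: FALL, name: "Lateral fall while sitting, caused by fainting", nominal_duration: 15, long_record: false}
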