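symptom	category
Joint redness, swelling, heat, and pain	primary
Frequent episodes of joint pain	primary
Fever and heaviness	primary
Dysphoria and restlessness	secondary
Abdominal distension	secondary
Bitter mouth	secondary
Halitosis	secondary
Sticky stool	secondary
Red tongue	tongue_pulse
Yellow and greasy tongue coating	tongue_pulse
Wiry-slippery pulse or slippery-rapid pulse	tongue_pulse
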