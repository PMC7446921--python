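# Symptom -> category dictionary used for category summaries.
#
# The nine categories are: general; lung and heart; skin; EENT (eyes, ears,
# nose, and throat); GI; nerves and muscle; reproductive; blood system;
# psychological.
#
# Memberships below are package defaults chosen on clinical common sense;
# they are editable data, not fixed facts about any particular cohort.
sore_throat: EENT
headache: nerves and muscle
difficulty_speaking: nerves and muscle
cough: lung and heart
itchy_or_burning_eyes: EENT
stress: psychological
shortness_of_breath: lung and heart
anxiety_worry: psychological
fatigue: general
sinus_infection: EENT
dry_skin: skin
difficulty_sleeping: general
rash: skin
depressed_mood: psychological
sinus_pain: EENT
nausea: GI
diarrhea: GI
abdominal_pain: GI
joint_pain: nerves and muscle
muscle_aches: nerves and muscle
numbness_tingling: nerves and muscle
dizziness: nerves and muscle
nosebleed: EENT
ear_ringing: EENT
eye_irritation: EENT
wheezing: lung and heart
chest_pain: lung and heart
palpitations: lung and heart
itchy_skin: skin
hair_loss: skin
weakness: general
fever: general
weight_change: general
menstrual_irregularity: reproductive
reduced_libido: reproductive
easy_bruising: blood system
anemia: blood system
irritability: psychological
memory_problems: nerves and muscle
loss_of_smell: EENT
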