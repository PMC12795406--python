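perception
cognition
emotion
utterance
motion
caused_motion
transfer
contact
impact
ingestion
creation
destruction
possession
existence
location
posture
manipulation
pursuit
social_interaction
communication
desire
evaluation
naming
counting
reading
writing
playing
washing
dressing
cooking
feeding
helping
hindering
searching
finding
showing
giving
taking
sending
bringing
carrying
holding
opening
closing
breaking
building
measuring
attention
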