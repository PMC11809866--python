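# Synthetic demo lexicon set for the screening classifiers.
# 84 single-feature lexicons in five groups (24/29/12/10/9):
# linguistic dimensions, affective processes and emotions, personal
# concerns and biological processes, suicide-risk vocabulary, and
# eating-disorder vocabulary. Term lists are illustrative stand-ins
# written for testing; swap in clinically curated lists for real use.
linguistic_dimensions:
  first_person_singular:
  - i
  - me
  - my
  - mine
  - myself
  first_person_plural:
  - we
  - us
  - our
  - ours
  second_person:
  - you
  - your
  - yours
  third_person:
  - he
  - she
  - they
  - them
  - his
  - her
  impersonal_pronouns:
  - it
  - its
  - that
  - this
  - those
  articles:
  - a
  - an
  - the
  prepositions:
  - in
  - 'on'
  - at
  - with
  - from
  - into
  auxiliary_verbs:
  - is
  - are
  - was
  - were
  - have
  - has
  - had
  common_adverbs:
  - very
  - really
  - quite
  - just
  - so
  conjunctions:
  - and
  - but
  - or
  - because
  - although
  negations:
  - 'no'
  - not
  - never
  - none
  - nothing
  common_verbs:
  - go
  - get
  - make
  - take
  - see
  past_focus:
  - was
  - did
  - went
  - ate
  - felt
  present_focus:
  - am
  - is
  - feel
  - eat
  - think
  future_focus:
  - will
  - gonna
  - tomorrow
  - soon
  - plan
  interrogatives:
  - what
  - why
  - how
  - when
  - where
  numbers:
  - one
  - two
  - three
  - hundred
  - thousand
  quantifiers:
  - few
  - many
  - much
  - lots
  - some
  comparatives:
  - better
  - worse
  - more
  - less
  - thinner
  certainty:
  - always
  - definitely
  - certainly
  - sure
  tentative:
  - maybe
  - perhaps
  - guess
  - might
  causation:
  - because
  - cause
  - effect
  - hence
  - therefore
  discrepancy:
  - should
  - would
  - could
  - ought
  fillers:
  - like
  - um
  - uh
  - well
  - you know
affective_processes:
  positive_emotion:
  - happy
  - glad
  - nice
  - good
  - great
  negative_emotion:
  - bad
  - awful
  - terrible
  - horrible
  - nasty
  anxiety:
  - anxious
  - worried
  - nervous
  - panic
  - afraid
  anger:
  - angry
  - mad
  - furious
  - rage
  sadness:
  - sad
  - crying
  - tears
  - grief
  - down
  joy:
  - joy
  - delight
  - cheerful
  - smile
  fear:
  - fear
  - scared
  - terrified
  - dread
  disgust:
  - disgusting
  - gross
  - revolting
  - sick
  surprise:
  - surprised
  - shocked
  - astonished
  - sudden
  trust:
  - trust
  - reliable
  - honest
  - faith
  anticipation:
  - expect
  - await
  - looking forward
  - hope
  shame:
  - ashamed
  - shame
  - embarrassed
  - humiliated
  guilt:
  - guilty
  - guilt
  - regret
  - sorry
  - fault
  loneliness:
  - lonely
  - alone
  - isolated
  - abandoned
  hopelessness:
  - hopeless
  - pointless
  - no way out
  - give up
  worthlessness:
  - worthless
  - useless
  - failure
  - nobody
  irritability:
  - irritated
  - annoyed
  - bothered
  - snappy
  mood_swings:
  - mood swings
  - ups and downs
  - unstable
  emotional_numbness:
  - numb
  - empty
  - nothing inside
  - hollow
  crying:
  - cry
  - cried
  - sobbing
  - weeping
  despair:
  - despair
  - desperate
  - anguish
  - misery
  relief:
  - relief
  - relieved
  - unburdened
  - calm down
  gratitude:
  - grateful
  - thankful
  - thanks
  - appreciate
  love:
  - love
  - beloved
  - adore
  - dear
  hate:
  - hate
  - hated
  - loathe
  - detest
  envy:
  - envy
  - jealous
  - envious
  frustration:
  - frustrated
  - stuck
  - fed up
  calmness:
  - calm
  - peaceful
  - relaxed
  - serene
  optimism:
  - hopeful
  - optimistic
  - bright side
  - better days
personal_concerns_biological:
  work:
  - work
  - job
  - boss
  - office
  - career
  leisure:
  - movie
  - music
  - game
  - party
  - fun
  home:
  - home
  - house
  - family
  - room
  - kitchen
  money:
  - money
  - cash
  - price
  - cost
  - pay
  religion:
  - god
  - pray
  - church
  - faith
  - spiritual
  death:
  - death
  - die
  - dead
  - funeral
  - grave
  health_concerns:
  - doctor
  - hospital
  - medicine
  - clinic
  - therapy
  body_states:
  - tired
  - dizzy
  - cold
  - weak
  - faint
  ingestion:
  - eat
  - ate
  - meal
  - drink
  - swallow
  sexuality:
  - sexy
  - attractive
  - dating
  - romance
  sleep:
  - sleep
  - insomnia
  - awake
  - dream
  - nap
  physical_pain:
  - pain
  - ache
  - hurt
  - sore
  - cramp
suicide_risk_vocabulary:
  self_harm_refs:
  - cut
  - cutting
  - scars
  - burn myself
  - hurt myself
  suicidal_ideation:
  - kill myself
  - end it
  - suicide
  - not worth living
  burden_refs:
  - burden
  - better off without me
  - in the way
  isolation_refs:
  - no one
  - nobody cares
  - shut out
  - withdrawn
  farewell_refs:
  - goodbye
  - last time
  - farewell
  - final note
  method_refs:
  - pills
  - overdose
  - rope
  - jump
  prior_attempt_refs:
  - tried before
  - last attempt
  - again
  impulsivity_refs:
  - impulse
  - sudden urge
  - without thinking
  substance_refs:
  - alcohol
  - drunk
  - drugs
  - high
  - smoke
  crisis_refs:
  - crisis
  - emergency
  - hotline
  - help me now
eating_disorder_vocabulary:
  food_refs:
  - food
  - snack
  - dinner
  - lunch
  - breakfast
  caloric_counting:
  - calories
  - kcal
  - calorie count
  - burned calories
  fasting_refs:
  - fasting
  - fast
  - skip meals
  - water fast
  - ayuno
  purging_refs:
  - purge
  - purging
  - throw up
  - laxatives
  excessive_exercise:
  - workout
  - burn
  - cardio
  - exercise more
  - no rest
  body_image:
  - fat
  - thin
  - skinny
  - mirror
  - body check
  - gorda
  weight_refs:
  - weight
  - weigh
  - kilos
  - pounds
  - scale
  - peso
  thinspiration_refs:
  - thinspo
  - proana
  - promia
  - edtwt
  - goal weight
  diet_culture:
  - diet
  - detox
  - cheat day
  - clean eating
  - dieta
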