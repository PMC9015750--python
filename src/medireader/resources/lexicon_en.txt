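# Small general-English lexicon standing in for a full dictionary lookup
# (presence here drives the in-lexicon feature). User-overridable.
the
a
and
of
to
in
is
was
for
with
on
that
this
cold
fever
pain
wound
blood
heart
bone
skin
head
hand
arm
leg
eye
ear
nose
mouth
chest
stomach
back
neck
foot
knee
hip
tooth
teeth
hair
nail
muscle
nerve
brain
lung
liver
kidney
sleep
food
water
doctor
nurse
hospital
medicine
pill
shot
cut
burn
bruise
swelling
itch
rash
cough
sneeze
cold
flu
cancer
sugar
pressure
weight
height
age
man
woman
child
baby
old
young
sick
well
healthy
weak
strong
tired
dizzy
numb
sore
broken
healing
bleeding
breathing
eating
walking
running
sitting
standing
lying
common
rare
small
large
high
low
fast
slow
good
bad
new
long
short
open
closed
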