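# Synthetic stand-in pool for the word-oddball manipulation-check condition:
# 72 familiar 4-letter English words, each ending in a consonant. The original
# study's word list is not distributed with this package; this list matches its
# structural constraints (length, final consonant), not its lexical statistics.
roll
help
soft
last
ship
stop
hold
park
jump
town
bird
farm
milk
hand
door
fish
ring
book
rain
wind
star
moon
king
leaf
song
duck
frog
goat
lamb
wolf
bear
lion
seal
crab
corn
salt
gold
iron
wool
silk
sand
rock
hill
pond
road
path
wall
roof
desk
lamp
sock
boot
coat
belt
ball
doll
drum
horn
bell
card
coin
dish
fork
nail
tail
foot
hair
neck
back
head
year
food
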