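# Synthetic stand-in pool for the base stream of the manipulation-check
# condition: 72 unique unpronounceable 4-consonant strings (no vowels).
fzvs
rzml
pgqs
wgvk
cmgj
dfvn
fsmb
rtgs
frvt
prwm
fdmz
tmbf
rjxp
xmrp
sghv
thmp
gqjd
kndm
zcbs
ldfc
mpjd
fxrk
qmbj
bfsw
bpht
shfl
gwnd
jmzk
dngh
xvbn
kwzv
pjtn
vdbg
xqgh
rgtx
mrkx
ntxp
ghtr
mtlg
rftm
kjwd
qzcn
hrfc
qjmw
bsfx
tfvd
dstz
rshb
bckz
gwqp
zndx
zltm
lzxw
wjnb
fjmr
qrxt
dlwb
vnzj
qnzm
hzmx
qcvz
lqng
zjsf
hxjs
crmk
fwln
xpnl
whzs
kdnc
jgbh
wflt
wpdn
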