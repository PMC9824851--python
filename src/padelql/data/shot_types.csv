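code,spanish_name,aliases
s,servicio,serve
d,derecha,drive;forehand
r,revés,backhand
ad,alambrada derecha,right mesh;right fence
ar,alambrada revés,left mesh;left fence
pld,pared lateral de derecha,side wall drive
plr,pared lateral de revés,side wall backhand
spd,salida de pared de derecha,off the wall forehand
spr,salida de pared de revés,off the wall backhand
bpd,bajada de pared de derecha,off the wall forehand smash
bpr,bajada de pared de revés,off the wall backhand smash
dpa,doble pared que abre,double wall opening
dpag,doble pared que abre con giro,double wall opening with rotation
dpc,doble pared que cierra,double wall closing
cp,contrapared,back wall boast
vd,volea de derecha,drive volley;forehand volley
vr,volea de revés,backhand volley
b,bandeja,defensive smash
djd,dejada,stop volley;drop shot
r1,remate,smash
r2,finta de remate,fake smash
r3,remate por 3,smash out by 3
r4,remate por 4,smash out by 4
cd,contra-ataque de derecha,forehand counter-attack
cr,contra-ataque de revés,backhand counter-attack
cpld,contrapared lateral derecha,right wall boast
cplr,contrapared lateral izquierda,left wall boast
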